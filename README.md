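# chillreq

Genotype-specific **chilling requirements (CR)** for temperate fruit-tree
progenies, estimated from long-term bloom-date and daily temperature
records via PLS regression.

Temperate fruit trees (apricot, peach, cherry, apple, ...) must
accumulate a genotype-specific amount of winter cold before dormancy can
break; selecting cultivars whose CR matches a growing region is central
to breeding under a warming climate.  Measuring CR in the lab (weekly
shoot forcing) does not scale to the hundreds of seedlings in a breeding
progeny.  `chillreq` automates the statistical alternative: for each
genotype it regresses bloom day-of-year on the season-aligned daily chill
accumulation series by partial least squares (PLS), delineates the
effective chilling period as the span of consecutive days with **negative
model coefficients and VIP ≥ 0.8** (capped one day before the genotype's
median bloom date), and then accumulates **Chilling Hours, Utah Chill
Units and Dynamic-Model Chill Portions** over that period in every
season.  The result is a standardized genotype × season CR table ready
for downstream use (QTL mapping, parent selection).

The stages in between are the field-standard ones: wide bloom tables
(`Genotype`, `BD12` ... columns, `*` marking unusable seasons) are
validated, filtered and reshaped; daily Tmin/Tmax records are
quality-checked and gap-filled; hourly temperatures are reconstructed
from daily extremes with the daytime-sine / nocturnal-log curve and
latitude-based sunrise/sunset.  See `docs/methods.md` for the models and
all formulas.

## Worked example

Generate a synthetic progeny with known ground truth and run the full
workflow (a real study would pass its own bloom/weather files):

```sh
chillreq simulate --n-genotypes 20 --first-year 2011 --last-year 2019 \
    --bloom-noise-sd 0 --seed 0 --out sim
chillreq run --bloom sim/bloom.csv --weather sim/weather.csv \
    --latitude 38.11 --out results
```

`results/` then contains per-genotype PLS files (`pls/pls_1_1.csv`, ...),
the delineated windows, the CR table and a run manifest.  Joining the
windows and the CR summary with the simulation's ground truth:

```
          Start  End  CP_mean  CH_mean  CU_mean  TrueCR
Genotype
1_1         -60    6     32.2    331.9    516.5    31.0
1_10        -57  -20     15.4    124.5    209.6    19.9
1_11        -59  -21     15.0    119.1    193.9    25.0
```

`Start`/`End` are season-relative day indices (Nov 1 = −60, Jan 1 = +1):
genotype `1_1`'s chilling period runs from Nov 1 to Jan 6, and over it
the tree accumulated on average 32.2 Chill Portions, 331.9 Chilling Hours
and 516.5 Utah Chill Units per season — its estimated CR, here close to
the simulated true value of 31.0 CP.  Every delineated window start falls
within a few days of the true chill onset (Nov 1).  Individual CR
magnitudes are less sharply resolved: with only 8 seasons the window end
localizes the progeny-wide dormancy-release transition, so per-genotype
CP values compress towards the population mean (compare `1_10`/`1_11`
above); `docs/methods.md` discusses this resolution limit and why the CR
table is best read as a selection phenotype.

The same objects are available as library functions
(`chillreq.run_pipeline`, `chillreq.fit_pls`,
`chillreq.delineate_chill_window`, ...), and `chillreq preprocess` /
`chillreq weather-qc` expose the two preprocessing stages separately.

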