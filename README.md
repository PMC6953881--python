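# actidays

How many days must a person wear an accelerometer before the average of
their daily physical-activity (PA) measures reliably represents their
*habitual* activity? `actidays` answers that question end to end for
wrist-worn, raw-acceleration protocols: it processes tri-axial signals into
ENMO-based daily constructs, estimates the single-day reliability of each
construct with a one-way intraclass correlation, and steps it up with the
Spearman–Brown prophecy to find the minimum number of monitoring days at a
chosen reliability target. A synthetic-cohort generator with known ground
truth makes every stage testable without access to cohort recordings.

It is aimed at epidemiologists and movement scientists planning or
re-analysing 24-h wrist accelerometry studies (the kind collected with
GENEActiv/Axivity-class devices at ~85.7 Hz, ±8 g).

## The model

**Signal → constructs.** Raw samples are autocalibrated against local
gravity (still windows must have vector magnitude 1 g), screened for
out-of-range values, and summarised per 5-s epoch as ENMO
(*Euclidean Norm Minus One*):

```
ENMO = max(0, sqrt(x² + y² + z²) − 1 g)        (epoch-averaged, in mg)
```

Non-wear is detected from sustained per-axis stillness (60-min windows,
15-min steps; SD < 13 mg and range < 50 mg on ≥ 2 axes). Per calendar day
(valid at ≥ 16 h wear) three constructs are computed: **overall PA** (mean
ENMO over wear epochs, mg), **LPA** (minutes at 50–100 mg) and **bouted
MVPA** (minutes in ≥ 10-min bouts with ≥ 80 % of epochs strictly above
100 mg). The analytical sample keeps subjects with ≥ 6 valid days and
retains the first 6, giving a balanced subjects × days matrix per
construct.

**Constructs → days needed.** On a balanced n × k matrix, the single-day
reliability is the one-way random-effects, single-measure ICC,

```
ICC(1,1) = (MSB − MSW) / (MSB + (k − 1)·MSW),
```

and the reliability of a k-day average follows the Spearman–Brown
prophecy,

```
r_k = k·r₁ / (1 + (k − 1)·r₁),
```

inverted for the smallest k with r_k strictly above the target (0.70 by
default): `k = ceil(target·(1 − r₁) / (r₁·(1 − target)))`.

## Worked example

The core arithmetic, straight from the library:

```python
>>> from actidays import spearman_brown, min_days
>>> spearman_brown(0.44, 6)     # six-day reliability from a 0.44 single day
0.825
>>> min_days(0.44, 0.70)        # days needed to exceed 0.70
3
>>> min_days(0.54, 0.70)
2
```

A single-day ICC of 0.44 means 44 % of the day-level variance reflects the
stable between-person construct; averaging six such days lifts that to
0.825 (printed as 0.83 at two decimals), and three days already exceed the
conventional 0.70 bar, while a 0.54 single-day coefficient needs only two.

The full pipeline on a simulated cohort (100 subjects × 7 days of 5-s
epochs; the sklearn-style `SpearmanBrownReliability` estimator runs under
the hood):

```
$ actidays all --seed 11 --out out/
overall: icc1=0.641 min_days=2
lpa: icc1=0.573 min_days=2
mvpa: icc1=0.369 min_days=4
```

i.e. for this synthetic cohort two monitoring days suffice for overall PA
and LPA, while bouted MVPA — a sparser, noisier behaviour — needs four.
`out/` also receives the day summaries, the balanced construct matrices,
the reliability curves for 1–6 days, day-of-week/weekend medians with
Kruskal–Wallis and Mann–Whitney tests, and a ground-truth manifest; two
runs with the same seed are byte-identical. `simulate`, `process`,
`reliability` and `descriptives` run the stages separately over CSV files
(raw recordings as `timestamp_iso8601,x_g,y_g,z_g`; see `actidays --help`).

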