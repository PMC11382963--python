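# mobstates

Predictability states of human mobility from check-in trajectories.

How predictable is a person's movement?  Treating a user's check-in history
as a symbol sequence `X = {x(1), …, x(T)}` over their visited venues `V`,
two entropies quantify the uncertainty of the next location:

* the **uncorrelated entropy** — the Shannon entropy of the visitation
  frequencies, ignoring order:

  `H_u = − Σ_{x∈V} p(x) log₂ p(x)`

* the **entropy rate** — a nonparametric Lempel–Ziv estimate that also uses
  the temporal order of visits:

  `H_c = N log₂ N / Σ_i Λ_i`

  where `N` is the number of recorded moves and `Λ_i` is the length of the
  shortest substring starting at position `i` that never occurred earlier in
  the sequence.

Either entropy converts to a **predictability bound** `Π` — the best success
rate any next-location predictor could achieve — by inverting Fano's
inequality

  `H = B(Π) + (1 − Π) log₂(S − 1)` ,  `B(x) = −x log₂ x − (1−x) log₂(1−x)`,

with `S` the number of distinct locations visited.

A single whole-history `Π`, however, averages over strongly heterogeneous
behaviour.  This package computes predictability as a *state* that varies
with context:

* **Hour-of-week profiles** — check-ins pooled into 168 hourly slots
  (24 h × 7 days) across weeks, with `Π_u` per slot; population means,
  spreads and stratification by activity level (distinct locations `S`,
  radius of gyration `r_g`, monthly check-in rate `f̄_c`).
* **Observation windows** — the weekly cycle tiled into `w`-hour bins;
  per-user mean `Π_u` as a function of `w`, and the mode of its population
  distribution (which saturates around daily windows).
* **Spectral modes** — a Morlet continuous-wavelet decomposition of each
  user's weekly predictability profile, with red-noise (AR(1)) chi-square
  significance, classifying each user's dominant periodicity as circadian
  (24 h), circasemidian (12 h) or 6 h.
* **Location context** — predictability restricted to venue categories
  (Home/Work, Food, Nightlife, …) and an ordinary-least-squares model that
  estimates a user's correlated predictability `Π_c` from nothing but their
  relative category visit frequencies.

Readers are provided for the common LBSN check-in dialects (SNAP-style TSV,
Weeplaces-style CSV with categories, generic CSV via a column map), and a
synthetic cohort generator with known ground truth (designed periodicities,
designed regression coefficients, analytic Markov entropy rates) makes every
stage testable without downloading data.

## Worked example

```python
import numpy as np
from mobstates import (CohortSpec, gen_cohort, sequence_predictability,
                       population_profile, mode_shares)

ds, truth = gen_cohort(CohortSpec(n_users=50, weeks=16, seed=7))
res, pi_u, pi_c = sequence_predictability(ds.trajectories["u0000"].symbols())
print(f"user u0000: N={res.N} S={res.S} "
      f"H_u={res.H_u:.2f} H_c={res.H_c:.2f} bits  "
      f"Pi_u={pi_u.Pi:.2f} Pi_c={pi_c.Pi:.2f}")

prof = population_profile(ds)
byhour = prof.mean.reshape(7, 24)
print(f"population Pi_u: night (03-06h) {np.nanmean(byhour[:, 3:6]):.2f}, "
      f"midday (12-15h) {np.nanmean(byhour[:, 12:15]):.2f}")

shares, _ = mode_shares(ds)
print("dominant wavelet modes:", {k: round(v, 2) for k, v in shares.items()})
```

prints

```
user u0000: N=824 S=22 H_u=3.36 H_c=2.77 bits  Pi_u=0.46 Pi_c=0.59
population Pi_u: night (03-06h) 0.94, midday (12-15h) 0.48
dominant wavelet modes: {'24h': 1.0}
```

Accounting for the visit order lowers the entropy (3.36 → 2.77 bits) and
raises the predictability bound (0.46 → 0.59); the population is far more
predictable at night, when everyone is at a single venue, than at midday;
and every user of this default cohort is built circadian, which the wavelet
classifier recovers.

The same pipeline is available from the shell:

```sh
mobstates simulate --n-users 50 --weeks 16 --seed 7 --out cohort.csv
mobstates entropy cohort.csv --out entropy.csv
mobstates states cohort.csv --window 24 --out-slots slots.csv --out-users users.csv
mobstates spectrum cohort.csv --out-spectrum spectrum.csv --out-users modes.csv
mobstates context cohort.csv --out-dist dist.csv --out-model model.json --out-residuals resid.csv
```

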