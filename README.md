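# p53trap

Computational toolkit for **abundance-driven bifunctional cytotoxin** design
against mutant p53. Cancers with missense *TP53* mutations accumulate p53
protein (half-life stretches from ~16 minutes to many hours because the MDM2
feedback loop is broken). A membrane-permeable bifunctional molecule that
binds p53 on one end and an essential enzyme's inhibitor on the other is
trapped inside exactly those cells, concentrating the toxin where mutant p53
is abundant. This package implements the quantitative arms of that strategy
for computational biologists and chemical biologists:

- **`p53trap.kinetics`** — an ODE model of compound trapping. With constant
  extracellular compound `[M_A]`, intracellular free compound `[M_B]`, free
  target `[P]` and complex `[MP]`:

  ```
  d[M_A]/dt = 0
  d[M_B]/dt = −k_diff[M_B] + k_diff[M_A] − k_bind[M_B][P] + k_unbind[MP]
  d[MP]/dt  =  k_bind[M_B][P] − k_unbind[MP] − [MP]·ln2/t½
  d[P]/dt   = −k_bind[M_B][P] + k_unbind[MP] − [P]·ln2/t½ + r_prod
  ```

  with `r_prod = P_ss_ref·ln2/t½_ref` calibrated once (1 µM at 24 h) and held
  fixed, so the steady-state protein pool — and the trapped compound — scales
  with the target's half-life. A closed-form steady state (quadratic in
  `[MP]`) serves as an independent oracle for the stiff integrator.
- **`p53trap.screen`** — differential CRISPR-dependency / proteomics screens
  between TP53-mutant and WT cell lines (Welch t-test, Benjamini–Hochberg),
  with the hit rules `mean_mut < −0.5 ∧ Δ < −0.2` (dependency) and
  `Δz > 2 ∧ q < 0.05` (proteomics).
- **`p53trap.nominate`** — payload-target nomination: filter genes to mean
  Chronos ≤ −2 and protein abundance ≤ 920 nM (the p53 level in 293T cells),
  rank by `log10(abundance in nM) + mean Chronos`, ascending.
- **`p53trap.phasing`** — cis/trans calling for two transcript variants from
  read pairs spanning both positions (SAM input via pysam).
- **`p53trap.doseresponse`** — vehicle normalization, 4PL EC50 fits, observed
  Emax conventions for competition and NanoBiT readouts, and 2^−ΔΔCt qPCR
  quantification.
- **`p53trap.synthetic`** — seeded generators for every input shape above, so
  the full pipeline runs and is tested without any external downloads.

## Worked example

How much more compound does a cell expressing long-lived (17 h) target trap
compared with short-lived (16 min) wild-type-like target, at a 0.1 nM dose?

```python
from p53trap import KineticParameters, simulate, accumulation_fold
from p53trap.kinetics import HOUR, MINUTE

for t_half in (16 * MINUTE, 17 * HOUR):
    p = KineticParameters(t_half=t_half, M_A0=1e-10)
    traj = simulate(p)  # integrate to 600 h
    m_b, mp = traj.final_state[1], traj.final_state[3]
    print(f"t1/2 {t_half/3600:5.2f} h: intracellular {m_b + mp:.3e} M, "
          f"fold {accumulation_fold(traj):8.1f}")
```

prints

```
t1/2  0.27 h: intracellular 1.293e-09 M, fold     12.9
t1/2 17.00 h: intracellular 6.205e-07 M, fold   6205.3
```

The 17 h cell holds 6205× the extracellular concentration versus 12.9× for
the 16 min cell — a log10 ratio of 2.68, i.e. between two and three orders
of magnitude of selective accumulation from protein stability alone.

The same operations are exposed on the command line:

```sh
p53trap simulate --t-half 17h --dose 1e-10M
p53trap sweep --t-half-grid 16min,1h,17h --dose-grid 1e-11M,1e-10M,1e-9M --out sweep.csv
p53trap gen reads --phase trans --seed 1 --out-dir data/
p53trap phase --alignments data/reads.sam --site1 100:A>G --site2 180:C>T
```

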