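# ivmotility

Quantification of T-cell behavior in intravital tumor imaging: from
multi-channel time-lapse stacks (or ground-truthed synthetic equivalents) to
per-cell motility metrics, morpho-dynamic elongation, four-quadrant
behavioral classification, periphery→core spatial heterogeneity, and
cohort-level statistics.

## The problem

Intravital two-photon microscopy of adoptively transferred, GFP-labelled
cytotoxic T-cells in a tumor (mCherry tumor cells, second-harmonic collagen
signal marking the stromal periphery) produces 3D+t stacks in which
individual cells must be detected, tracked, and summarised — and in which
treatment effects (e.g. immune-checkpoint blockade) appear as shifts in
motility, morphology and spatial distribution. This package implements that
quantification chain as a tested, reusable library, plus a synthetic-data
generator that emulates the statistical structure of such experiments so
every stage can be validated against known ground truth.

## The core quantities

For a track with positions $p_0 \dots p_{n-1}$ observed over duration $T$
minutes:

- displacement $d = \lVert p_{n-1} - p_0 \rVert$ (μm),
- path length $L = \sum_i \lVert p_{i+1} - p_i \rVert$ (μm),
- mean velocity $v = d / T$ (μm/min) — the displacement-based convention;
  the conventional path speed $L/T$ is exported as a supplementary column,
- meandering index $\mathrm{MI} = d / L \in [0, 1]$; 1 is a perfectly
  straight track, values near 0 indicate confined or looping motion.

Tracks are classified into four behavioral quadrants by cohort-level
thresholds $(v^*, \mathrm{MI}^*)$ — the unweighted means of $v$ and MI over
all tracks of all arms: Q1 fast/low-MI (migrating, returning), Q2
fast/high-MI (directional, sustained), Q3 slow/low-MI (low motility), Q4
slow/high-MI (non-sustained). Cell shape is summarised by the elongation
index $E = $ fitted-ellipse major/minor axis ratio, and infiltration
heterogeneity by the Pearson kurtosis $K = m_4 / m_2^2$ of cell positions
along the periphery→core axis ($K = 1.8$ for uniform infiltration, higher
when cells concentrate toward the core). Tumor volumes from caliper axes
use the ellipsoid estimate $V = (\pi/6)\,abc$.

## Worked example

```python
from ivmotility import MotionModel, simulate_track, track_metrics

for kind in ["ballistic", "levy", "confined_brownian", "stationary_probing"]:
    model = MotionModel(kind, speed_scale=4.6, persistence=0.6,
                        truncation_step=8.0, confinement_radius=10.0)
    m = track_metrics(simulate_track(model, n_frames=61, dt=0.5, seed=1))
    print(f"{kind:<20} v={m.v_um_min:.3f} um/min  MI={m.mi:.3f}")
```

prints

```
ballistic            v=4.600 um/min  MI=1.000
levy                 v=2.843 um/min  MI=0.735
confined_brownian    v=0.186 um/min  MI=0.057
stationary_probing   v=0.016 um/min  MI=0.009
```

— a ballistic cell moves at exactly its speed scale with MI = 1 (straight
track), a truncated-Lévy walker keeps substantial net displacement, while
confined and probing cells accumulate path length without displacing, so
their displacement-based velocity and MI collapse toward 0.

The full synthetic study (three arms: fast vehicle control, two slower and
more numerous treated arms) runs end to end — render, project, debleach,
register, detect, track, filter, classify, summarise:

```bash
ivmotility demo --seed 1 --out out/
```

which reports per-arm mean velocity ± SEM (control fastest), the
Kruskal–Wallis/Dunn comparison across arms, quadrant counts, the spatial
kurtosis of cell positions, and writes all tables, figures and a manifest
of every parameter and seed. The `examples/` directory contains one short
narrative script per capability.

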