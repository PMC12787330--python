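# gearvoc

Quantifying how a fish was caught from the smell it gives off.

The way a fish is obtained — longline, hook and line, gillnets, purse seine,
trawl, or aquaculture rearing — leaves a chemical trace: stress, handling,
physical damage and diet all change the volatile organic compounds (VOCs)
the tissue releases after capture. An electronic nose (an array of
cross-sensitive metal-oxide gas sensors) records that volatile profile over
time. `gearvoc` implements the chemometric analysis of such recordings for
*Sparus aurata* (gilthead sea bream): it quantifies how far each acquisition
method deviates the VOC profile from the basal profile, and classifies the
gear of origin from single sensor readings. Because the underlying sensor
recordings are not publicly deposited, the package ships a first-class
synthetic-data generator with known ground truth, so every stage of the
analysis is testable end to end.

## The model

Recordings are assembled into a three-way tensor **X** ∈ ℝ^(I×J×K) (I time
instances × J = 35 sensor variables × K = 8 gears) and decomposed by
CP/PARAFAC with alternating least squares:

    X_ijk  ≈  Σ_r  ω_r · a_ir · b_jr · c_kr  +  E_ijk ,    r = 1…R

with unit-norm factor columns and the magnitudes absorbed into the weights
ω_r. Model adequacy is the cumulative explained variance

    VEC = 100 · (1 − ‖X − X̂‖²_F / ‖X‖²_F),

swept over ranks and many random initializations; the working rank is the
elbow of the mean VEC curve. The *impact* of gear k in one fitted model is
the L2 norm of its weighted gear-mode loadings,

    I_k = √( Σ_r (ω_r · c_kr)² ),

averaged over initializations with an empirical 95% CI, and re-expressed as
a *severity scale*: each gear's percentage increase over the minimum-impact
gear (the basal profile). Classification uses one feature vector per time
instance (35 standardized sensor values) with from-scratch random-subspace
KNN, kernel naive Bayes and random-subspace linear discriminant ensembles,
plus Monte-Carlo Shapley feature importances.

## Worked example

Run the full synthetic study at reduced scale — 260 time instances, 3
replicates per gear, rank sweep 1…8 with 10 seeds:

```python
import tempfile
from gearvoc import RunConfig, SimulationConfig, SplitSpec
from gearvoc.pipeline import run_all

config = RunConfig(
    simulation=SimulationConfig(n_time=260, n_replicates=3, true_rank=4, seed=1),
    ranks=list(range(1, 9)), n_seeds=10, base_seed=1001, default_rank=4,
    cp_tol=1e-6, cp_max_iter=400, split=SplitSpec(seed=1),
)
with tempfile.TemporaryDirectory() as tmp:
    report = run_all(config, tmp)
```

The report (also written as `report.json` / `report.md`, next to every
intermediate artifact) contains:

```
selected rank: 3          VEC at selected rank: 94.43%
baseline gear: Longline
  Aquaculture               51.88%
  Purse seine               41.90%
  Trawl                     37.35%
  Gillnet (single panel)    27.72%
  Gillnet (three panels)    26.23%
  Gillnet (two panels)      19.44%
  Hook and line              2.61%
  Longline                   0.00%
subspace KNN, 35 variables: val 97.88% / test 98.72%
```

Reading this: the elbow of the explained-variance curve selects rank 3; the
severity scale says aquaculture-reared fish deviate ~52% from the longline
basal profile while hook-and-line fish are nearly indistinguishable from it
(matching the generator's configured hierarchy — gears whose targets sit
within a few percent of each other, like the two gillnet variants here, can
swap within noise); and a subspace-KNN ensemble identifies the gear of a
single sensor reading with ~98% accuracy.

The same stages are scriptable from a shell:

```bash
gearvoc simulate   --config cfg.yaml --out raw/
gearvoc preprocess --in raw/ --out clean/
gearvoc decompose  --in clean/ --ranks 1:8 --seeds 10 --out models/
gearvoc impact     --models models/ --rank 3 --out impact/
gearvoc classify   --in clean/ --subset MQ-4,MQ-7 --out clf/
gearvoc run-all    --config cfg.yaml --out study/
```

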