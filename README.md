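# pointal — point-supervised active learning for crop detection

Training an object detector to find and count panicles (wheat ears, sorghum
heads) in field images needs thousands of tightly drawn bounding boxes, and a
single 500×500 tile can hold 25–100+ objects. Boxes are expensive: drawing
and verifying one takes ≈34.5 s, while clicking an object's centre takes
≈3 s. `pointal` implements an active-learning strategy that spends the box
budget only where the detector is actually uncertain, using cheap centre
clicks as a guide.

The package is aimed at plant-phenotyping and detection researchers who want
to study annotation-efficient training loops without committing GPU weeks: it
ships a synthetic scene generator and a simulated two-stage detector, so the
whole pipeline runs in seconds on a CPU, and a detector contract
(`train` / `propose` / `detect`) for plugging in a real Faster R-CNN-style
model.

## The method

Three pools are maintained: labeled `D^L` (boxes), weakly labeled `D^W`
(centre clicks), unlabeled `D^U`. Each episode:

1. **Weak query.** A stage-1 criterion — random, least confidence
   `1 − max p`, margin `Σ(p₁ − p₂)`, or entropy `−Σ p log₂ p` over current
   detections — picks `b_W` images from `D^U`; the oracle clicks every object
   centre; the images move to `D^W`.
2. **Region proposal filtering (RPF).** The model's region proposals are run
   on `D^W`. A proposal is kept for click `w` only if it contains `w`, its
   centre is within `ε` of `w`, its area is ≤ `α`, and it contains no other
   click. Survivors form per-object score sets `P_iw`. `ε` is the 20th
   percentile of nearest-neighbour distances between box centres in the seed
   pool (rounded to a multiple of 10); `α` the 90th percentile of box areas
   (rounded to two significant figures).
3. **Uncertainty.** Per image `i`, with `p ∈ P_iw` the objectness scores:

   - max-variance `u^var_i = max_w (1/|P_iw|) Σ (p − mean(P_iw))²`
   - max-entropy `u^ent_i = max_w (1/|P_iw|) Σ −p log₂ p − (1−p) log₂(1−p)`
   - max-ent-var `u^ev_i = λ₁ u^ent_i + λ₂ u^var_i`, default `λ = (1, 4)`
     since variance of probabilities is bounded by 0.25 (Bhatia–Davis) and
     binary entropy by 1, so ×4 puts both terms on a common [0, 1] scale.

   The `b_S` most uncertain weak images get boxes and move to `D^L`; the
   detector retrains.
4. **Costs.** Weak batch: `7.8·Q_W + 3·b_QW` seconds (per-image check +
   clicks). Strong promotion: `34.5·b_QS`. Standard pool-based AL pays
   `7.8·Q + 34.5·b_Q`. Click time is never charged twice.

Detection quality is AP@0.5IOU (greedy matching, monotone precision
envelope); count agreement is Pearson r and RMSE on per-image counts.

## Worked example

```python
from pointal import (ExperimentConfig, SceneParams, SimDetectorParams,
                     SimulatedDetector, generate_pool, run_experiment)

pool = generate_pool(300, SceneParams(), seed=0)          # synthetic tiles
cfg = ExperimentConfig(stage1="ent", stage2="mev", seed=1)  # method ent_mev
det = SimulatedDetector(SimDetectorParams(seed=1))
res = run_experiment(pool, det, cfg)

print(res.rpf_params)
for log in res.logs[:3] + res.logs[-1:]:
    print(f"ep {log.episode:2d}  |D^L|={log.n_labeled:3d}  AP={log.ap:.3f}  "
          f"hours={log.cumulative_seconds/3600:.2f}")
```

prints

```
RpfParams(epsilon=30.0, alpha=2500.0)
ep  0  |D^L|= 50  AP=0.710  hours=16.59
ep  1  |D^L|= 60  AP=0.734  hours=22.81
ep  2  |D^L|= 70  AP=0.755  hours=28.59
ep 10  |D^L|=150  AP=0.840  hours=55.00
```

`ε`/`α` were estimated from the 50-image seed pool. The log shows test-set
AP@0.5IOU climbing as strong labels accumulate, and the cumulative annotation
time in hours; episode 0 is the randomly seeded pool. On this benchmark the
`mev` variants reach AP 0.8 with fewer strong labels than random sampling
(compare a run with `stage1="rand", stage2="none"`).

The same pipeline is scriptable from the shell:

```bash
pointal simulate --n-images 100 --seed 0 --out data/
pointal tile --gt data/annotations.json --tile-size 250 --mode drop-annotation --out tiled.json
pointal run --config experiment.yaml --seed 1 --out runs/ent_mev/
pointal evaluate --pred pred.json --gt data/annotations.json --iou 0.5
pointal cost-report --log runs/ent_mev/episodes.csv
```

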