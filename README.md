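# avpercept

Data-driven Bayesian-network modeling of audiovisual spatial perception:
both the spatial percept and the temporal dynamics of the perception
process (the decision time) in a two-task localization experiment.

## The problem

In an audiovisual localization task a primary stimulus (a sound in the
acoustic task, a flash in the visual task) appears at one of five
azimuthal positions, sometimes accompanied by a secondary stimulus in
the other modality at an offset of 0, ±5 or ±10 deg. Subjects point to
the perceived position of the primary stimulus. Two phenomena structure
the data: in the acoustic task the visual accessory *captures* the
percept (ventriloquism — fusion of the multisensory information),
whereas in the visual task the acoustic accessory leaves the percept
untouched (segregation); and decision times — stimulus onset to
movement onset — are shorter for visual than acoustic targets and
shorter for bisensory than unisensory presentations, revealing
multisensory integration in the process dynamics even when the percept
shows none.

`avpercept` treats the trial variables as a six-node system — task `S`,
mode of presentation `M`, primary and secondary positions `X_P`, `X_S`,
normalized localization `X̂`, decision time `T` — and

1. **simulates** the full behavioral protocol (10 subjects × 2 tasks ×
   450 trials) with calibrated fusion, noise and log-normal timing;
2. **elicits the network structure** from the data: pairwise mutual
   information normalized by the joint entropy, compared against
   null-calibrated thresholds; conditional-MI pruning with
   permutation-calibrated thresholds; conservative collider detection
   and Meek propagation; context-specific-independence multinets;
3. **fits** the resulting hybrid factorization by maximum likelihood

       P(S) P(M) P(X_P) P(X_S|M,X_P) P(X̂|S,X_P,X_S) P(T|S,X_S)

   with multinomial, Gaussian (`X̂`) and log-normal (`T`) factors;
4. **evaluates** MAP inference of percept and decision time by exact
   leave-one-subject-out cross-validation, reporting coefficients of
   determination per primary position and for decision times collapsed
   into the three modes of presentation.

See `docs/methods.md` for the model, the calibration and the design
choices.

## Worked example

```python
from avpercept.synthetic_data import SimParams, simulate_dataset
from avpercept.preprocess import normalize_localizations
from avpercept.structure import ThresholdPolicy, elicit, factorization
from avpercept.evaluate import crossvalidate, r2_summary, r2_by_position

table = normalize_localizations(simulate_dataset(SimParams(seed=11)))

pdag = elicit(table, ThresholdPolicy(seed=0))
print(sorted(pdag.directed))
print(factorization(pdag))

cv = crossvalidate(table)
print({k: round(v, 2) for k, v in r2_summary(cv).items()})
print(r2_by_position(cv).round(2))
```

prints

```
[('S', 'T'), ('S', 'XHAT'), ('XP', 'XHAT'), ('XS', 'T'), ('XS', 'XHAT')]
[('S', ()), ('M', ()), ('XP', ()), ('XS', ('M', 'XP')), ('T', ('S', 'XS')), ('XHAT', ('S', 'XP', 'XS'))]
{'percept': 0.91, 'time': 0.6, 'time_collapsed': 0.92, 'percept_pooled': 0.97, 'time_pooled': 0.64}
     xp  r2_percept  r2_time
0 -10.0        0.90     0.56
1  -5.0        0.91     0.57
2   0.0        0.93     0.62
3   5.0        0.91     0.60
4  10.0        0.89     0.65
```

The directed edges say that the percept depends on both stimulus
positions and on the task, while the decision time depends on the task
and on the secondary position (through which the mode of presentation
is encoded) — and that percept and decision time are conditionally
independent given that context. The `percept` and `time` numbers are
cross-validated R² values between the model's MAP predictions and the
held-out subject's condition means, averaged over primary positions and
folds: the model predicts the percept very well (≈ 0.91) and the
decision time fairly well at single-cell resolution (≈ 0.60); grouping
the decision-time cells into unisensory / coincident / non-coincident
presentations removes most observation noise and raises the score to
≈ 0.92.

The same pipeline runs from the shell:

```
avpercept all --seed 17 --out run1/
```

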