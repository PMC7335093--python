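# fiberfilter

Discriminative fiber filtering for brain-stimulation network mapping.

Given a tractogram (TRK/TCK), binary stimulation volumes (NIfTI masks,
e.g. volumes of tissue activated around DBS electrodes) and clinical
outcomes, `fiberfilter` identifies the streamlines whose stimulation
discriminates good from poor responders and uses them as a predictive
model — in-sample, across independent cohorts, and against published
stereotactic targets.

For every streamline *f* with connected stimulation set *C(f)* and
unconnected set *U(f)*, the fiber weight is the pooled two-sample t
statistic on improvements *y*:

    T_f = ( mean(y_C) - mean(y_U) ) / ( s_p * sqrt(1/|C| + 1/|U|) )

A stimulation's aggregate score is `sum of T_f over connected valid
fibers / amplitude`, correlated with improvement (Pearson by default),
with p-values from Monte-Carlo permutation of the outcome vector
(add-one estimator, two-sided, seeded). Cross-cohort prediction fits the
weights on one cohort and evaluates score/outcome correlation on
another; a built-in table of eleven published OCD-DBS targets (MNI
coordinates and reported %-Y-BOCS improvements) supports a
literature-level check via spherical stand-in stimulation volumes.

Because patient DBS data cannot be redistributed, the package ships a
synthetic generator (`fiberfilter.synthetic`): a planted streamline
bundle plus incoherent background fibers, and cohorts of spherical
stimulations whose outcome is a noisy linear function of bundle overlap
(`improvement = 60·overlap + N(0, 10)` by default). Every stage of the
pipeline is tested against it with known ground truth. See
`docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
import fiberfilter as ff
from fiberfilter import synthetic, experiments

# default planted-bundle experiment: 200 planted + 2000 background fibers,
# 20 spherical stimulations, outcome = 60*overlap + N(0,10)
run = experiments.run_insample(seed=1)
print(f"in-sample Pearson r = {run.r:.3f}")
print("positive/negative fibers:", ff.count_signed(run.model))

auc = experiments.ranking_auc(run.is_planted, run.model.t_values)
print(f"planted-fiber ranking AUC = {auc:.3f}")

res = experiments.run_cross_replicate(seed=1, n_perm=1000)
print(f"cross-cohort r = {res.r:.3f}, p_perm = {res.p_perm:.4f}")
```

Output:

```
in-sample Pearson r = 0.822
positive/negative fibers: (236, 77)
planted-fiber ranking AUC = 0.918
cross-cohort r = 0.924, p_perm = 0.0010
```

The in-sample correlation says the amplitude-normalized sum of fiber
weights under each stimulation explains most outcome variance; the AUC
says the t-value ranking cleanly separates the causally planted bundle
from background fibers; the cross-cohort result shows a weight map fitted
on one electrode-placement distribution predicting outcomes under a
different one, with a permutation p at the resolution floor 1/1001.

The same pipeline is scriptable from the shell:

```sh
fiberfilter simulate --out run/sim --seed 1
fiberfilter fit     --tractogram run/sim/connectome.trk --cohort run/sim/cohortA.csv \
                    --mask-dir run/sim/cohortA_masks --out run/fit
fiberfilter predict --tractogram run/sim/connectome.trk --cohort run/sim/cohortB.csv \
                    --mask-dir run/sim/cohortB_masks --model run/fit/fiber_scores.tsv \
                    --out run/pred
fiberfilter export-tract --tractogram run/sim/connectome.trk \
                    --model run/fit/fiber_scores.tsv --out run/top20.trk --fraction 0.2
```

Each run writes a `manifest.json` (parameters, seed, input digests,
version) so every printed number is recomputable.

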