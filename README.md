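# arifuse

No-reference quality assessment for image fusion, built around the
Arimoto-entropy mutual-information metric **M_α**.

Image fusion merges two co-registered grayscale images — a multi-focus
pair with complementary in-focus regions, or a multi-modal pair such as
CT/MR — into one image that should keep the salient content of both.
Because no ground-truth "ideal" fusion exists, quality must be scored
from the fused image F and its sources A, B alone. `arifuse` is for
researchers and engineers who develop or benchmark fusion algorithms and
need objective scores that track visual quality.

## The metric

The Arimoto entropy of order α > 0 generalises Shannon entropy,

    A_α(p) = α/(α−1) · [1 − (Σᵢ pᵢ^α)^(1/α)]   →  Shannon (nats) as α → 1,

and induces a divergence D_α(p‖q) = α/(1−α)·[1 − (Σᵢ pᵢ^α qᵢ^(1−α))^(1/α)].
Applying it to the joint gray-level histogram of two images versus the
product of their marginals gives the Arimoto mutual information I_α, and
the fusion metric is the total Arimoto information the fused image
carries about its sources:

    M_α(A, B; F) = I_α(F, A) + I_α(F, B),      default α = 1.5.

Four standard comparison metrics ship alongside: Shannon-MI (bits),
normalised MI, Tsallis-MI (default order q = 1.85), and the
Petrovic/Xydeas edge-preservation score Q^AB/F ∈ [0, 1]. Six classical
fusion algorithms (averaging, PCA, Laplacian pyramid, contrast pyramid,
blockwise DCT, guided-filter two-scale) are included as test stimuli,
plus a seed-reproducible generator of synthetic multi-focus and
multi-modal pairs with known ground truth. See `docs/methods.md` for the
full model description.

## Worked example

Score fusion candidates on a synthetic multi-focus pair whose ground
truth is known, and compare the metric's ranking with the full-reference
quality order (ascending RMSE to the truth):

```python
import numpy as np
import arifuse as af

spec = af.SynthSpec(seed=0, blur_sigma=3.0)          # 256x256 pair, sigma = 3 px
a, b, truth = af.make_multifocus_pair(spec)
candidates = [("truth", truth)] + [(m, af.fuse(m, a, b))
                                   for m in ("gf", "dct", "lp", "average")]

tf = truth.astype_float()
rmse = {lab: float(np.sqrt(np.mean((img.astype_float() - tf) ** 2)))
        for lab, img in candidates}
reference = sorted(rmse, key=rmse.get)               # full-reference quality order

scored = [(lab, af.metric_arimoto(a, b, img).value) for lab, img in candidates]
report = af.rank_candidates("arimoto", scored, reference_rank=reference)
for row in report.rows:
    print(f"{row.rank}. {row.label:<8} M_1.5 = {row.value:.3f}")
print(f"kendall_tau = {report.kendall_tau:.2f}")
```

prints

```
1. truth    M_1.5 = 14.581
2. gf       M_1.5 = 13.419
3. lp       M_1.5 = 8.655
4. dct      M_1.5 = 5.857
5. average  M_1.5 = 5.166
kendall_tau = 1.00
```

The ground truth scores highest, the detail-preserving guided-filter and
pyramid fusions follow, and the detail-destroying average comes last; the
metric ordering agrees exactly with the full-reference order (τ = 1).
Values are in natural units; higher means more source information
retained.

The same workflow is available from the shell:

```sh
arifuse simulate --kind multifocus --seed 0 --out-dir demo
arifuse fuse demo/a.png demo/b.png --method gf -o demo/gf.png
arifuse score demo/a.png demo/b.png demo/gf.png
# metric: arimoto
# alpha: 1.5
# value: 13.419146 (nats)
# I(F,A): 6.585781
# I(F,B): 6.833365
```

`arifuse rank` ranks several candidates (with optional Kendall/Spearman
agreement against a reference order) and `arifuse sweep` evaluates M_α
over the standard 10-point α grid.

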