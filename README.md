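# pcbiplot

Software-agnostic principal component analysis and PC biplots, with an
executable grid of the identities that correct implementations must satisfy,
and emulators/auditors for the documented conventions of fifteen published
PCA/biplot routines.

## Why

PCA and biplots are implemented everywhere, and the implementations
disagree — not in their pictures, but in the numbers underneath: the
covariance divisor (n−1 vs n), what gets called an "eigenvalue" (often the
squared singular value ℓ² instead of λ), and extra scalings silently applied
to biplot coordinates. These choices are invisible until you check the
relationships that should hold between scores, loadings, singular values and
coordinates. This package is for analysts and methodologists who want those
relationships to be *checkable*: it computes PCA and biplots from first
principles and turns each identity into an executable verdict
(`exact` / `sign_flip` / `fail` / `skipped`).

## The model

For a column-centred data matrix **Y** (n observations × m features):

- Covariance route: **S** = **Y**ᵀ**Y**/(n−1); eigenpairs (λₖ, **v**ₖ) of
  **S**; scores **Z** = **Y V**.
- SVD route: **Y** = **U D V**ᵀ with singular values ℓₖ; **Z** = **U D**.
- The routes are linked by ℓₖ = √(n−1)·√λₖ, and Var(**z**ₖ) = λₖ.
- A biplot splits **D** between the two factors:
  **Y** = (**U D**^α)(**D**^{1−α}**V**ᵀ) = **A B**ᵀ, 0 ≤ α ≤ 1.
  α = 0 is the *PC biplot* (**A** = **U**, **B** = **V D**); α = 1 is the
  scores-and-loadings overlay (**A** = **Z**, **B** = **V**). Truncating to
  k components gives the best rank-k approximation (Eckart–Young).

PC-biplot geometry (α = 0, all components retained):

- ‖**b**ⱼ‖/√(n−1) = σ(yⱼ) — feature vector lengths ∝ standard deviations;
- cos θ(**b**ₐ, **b**ᵦ) = corr(yₐ, yᵦ) — feature cosines are correlations;
- corr(**z**ₖ, **y**ⱼ) = vⱼₖ√λₖ/√sⱼⱼ — loadings are *proportional*, not
  equal, to feature–PC correlations;
- (**y**ₕ−**y**ᵢ)ᵀ**S**⁻¹(**y**ₕ−**y**ᵢ) = (n−1)‖**u**ₕ−**u**ᵢ‖² —
  inter-observation distances are scaled Mahalanobis distances.

At display rank 2 the last three become approximations; the grid reports the
gap instead of a failure, and the gap shrinks monotonically to zero as the
retained rank grows.

## Worked example

Two datasets from the literature ship with the package: a 6×2 toy matrix and
an 11×4 excerpt of (unitised, desensitised) clinical-trial supply-chain data
— stockouts (STO), enrolment (ENR), clinics (CLI) and duration (DUR) for 11
trial protocols.

```python
import numpy as np
import pcbiplot as pb

X = pb.load_fixture("ctsc_table7").matrix
Y = pb.center(X)
model = pb.fit_pca(Y)                    # thin SVD under the hood
print(np.round(model.eigenvalues, 2))    # [0.23 0.12 0.02 0.01]
print(round(pb.variance_explained(model, 2), 3))   # 0.922

coords = pb.pc_biplot(Y, 2)              # alpha = 0, display rank 2
print(np.round(coords.B, 2))
# [[ 0.96  0.22]      STO
#  [ 0.9   0.03]      ENR
#  [ 0.74 -0.34]      CLI
#  [ 0.02  1.01]]     DUR

report = pb.run_grid(X)
print([(o.check_id, o.status) for o in report.outcomes])
# every identity: 'exact'
```

The two retained components carry 92.2% of the variance, so the
2-dimensional display is a faithful summary; DUR's coordinate vector is
nearly orthogonal to the other three, i.e. trial duration is uncorrelated
with the operational-complexity axis formed by STO/ENR/CLI.

Emulating a published convention and auditing it:

```python
res = pb.emulate(X, "princomp")          # covariance divisor n, not n-1
for v in pb.audit(X, res):
    print(v.artifact, v.symbol, v.detail)
# loadings    abs_match  equal after column sign flips
# eigenvalues mismatch   proportional to reference with scalar 0.909091
# scores      abs_match  equal after column sign flips
# ...
```

The same is available from the shell: `pcbiplot pca`, `pcbiplot biplot`,
`pcbiplot grid run`, `pcbiplot emulate`, `pcbiplot audit`, `pcbiplot synth`,
`pcbiplot fixtures export`. Exit codes: 0 all checks pass, 2 a check
failed, 1 input/usage error.

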