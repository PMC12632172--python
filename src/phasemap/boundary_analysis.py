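"""Campaign summaries: LDA separation of PS vs non-PS, field projections.

For high-dimensional campaigns the sampled points are split into "with
PS" (PS fraction >= 0.5) and "without PS" classes and a Fisher linear
discriminant is fitted on per-dimension standardized flows. The unit-norm
discriminant weights rank how strongly each solute drives phase
separation; the decision value is the equal-prior midpoint of the two
class means along the component. Raw-space coefficients are reported
alongside for users who want unstandardized units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .design_space import DesignSpace
from .errors import NonGridField, SingleClassInput
from .surrogate import PosteriorField
from .virtual_lab import ObservedSample


@dataclass(frozen=True)
class LDAResult:
    """Fisher discriminant summary of a labelled campaign."""

    weights: np.ndarray  # unit L2 norm, standardized-input space
    raw_coefficients: np.ndarray  # same direction in raw flow units
    decision_value: float  # midpoint rule on the component
    class_means: tuple[float, float]  # (non-PS, PS) projections
    names: tuple[str, ...]

    @property
    def variable_ordering(self) -> list[str]:
        """Variable names sorted by decreasing discriminant weight."""
        order = np.argsort(self.weights)[::-1]
        return [self.names[i] for i in order]

    def summary(self) -> str:
        ordering = " > ".join(self.variable_ordering)
        pairs = ", ".join(
            f"{n}: {w:+.3f}" for n, w in zip(self.names, self.weights)
        )
        return f"LDA component ({pairs}); influence ordering {ordering}"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": list(self.names),
                "standardized_weight": self.weights,
                "raw_coefficient": self.raw_coefficients,
            }
        )


def lda_component(
    samples: list[ObservedSample],
    space: DesignSpace,
    label_threshold: float = 0.5,
) -> LDAResult:
    """Fisher discriminant separating PS from non-PS samples.

    Inputs are standardized to zero mean / unit variance per dimension so
    the weight magnitudes are comparable across solutes; the sign is
    oriented so the PS class has the larger mean component.
    """
    X = np.array([s.composition.flows for s in samples], dtype=float)
    y = np.array([s.ps_fraction >= label_threshold for s in samples])
    if y.all() or not y.any():
        raise SingleClassInput("need both PS and non-PS samples for LDA")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd

    lda = LinearDiscriminantAnalysis(n_components=1)
    lda.fit(Z, y.astype(int))
    w = lda.coef_.ravel().astype(float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise SingleClassInput("degenerate discriminant (zero direction)")
    w = w / norm

    proj = Z @ w
    mean_neg = float(proj[~y].mean())
    mean_pos = float(proj[y].mean())
    if mean_pos < mean_neg:
        w = -w
        proj = -proj
        mean_neg, mean_pos = -mean_neg, -mean_pos
    return LDAResult(
        weights=w,
        raw_coefficients=w / sd,
        decision_value=0.5 * (mean_neg + mean_pos),
        class_means=(mean_neg, mean_pos),
        names=tuple(space.names),
    )


def project_field(
    field: PosteriorField,
    space: DesignSpace,
    keep_dims: list[int],
    reducer: str = "slice_at_mid",
) -> PosteriorField:
    """Reduce a full-grid posterior field to the ``keep_dims`` subspace.

    ``slice_at_mid`` fixes every dropped dimension at the grid midpoint;
    ``mean`` averages mu over dropped dimensions and RMS-averages sigma.
    Points of the returned field carry only the kept coordinates.
    """
    d = space.n_dims
    keep_dims = list(keep_dims)
    if not keep_dims or any(k < 0 or k >= d for k in keep_dims):
        raise ValueError("keep_dims must index design-space dimensions")
    if len(set(keep_dims)) != len(keep_dims):
        raise ValueError("keep_dims must be unique")
    n = round(len(field.points) ** (1.0 / d))
    if n**d != len(field.points):
        raise NonGridField("projection requires a full Cartesian grid")
    shape = (n,) * d
    mu = field.mu.reshape(shape)
    sigma = field.sigma.reshape(shape)
    pts = field.points.reshape(shape + (d,))

    drop = tuple(k for k in range(d) if k not in keep_dims)
    if reducer == "slice_at_mid":
        idx = [n // 2 if k in drop else slice(None) for k in range(d)]
        mu_r = mu[tuple(idx)]
        sigma_r = sigma[tuple(idx)]
    elif reducer == "mean":
        mu_r = mu.mean(axis=drop) if drop else mu
        sigma_r = (
            np.sqrt((sigma**2).mean(axis=drop)) if drop else sigma
        )
    else:
        raise ValueError("reducer must be 'slice_at_mid' or 'mean'")

    # kept coordinates at the midpoint slice (identical across any slice)
    idx = [n // 2 if k in drop else slice(None) for k in range(d)]
    pts_r = pts[tuple(idx)][..., keep_dims]

    # slicing leaves the kept axes in ascending-dimension order; permute
    # them to follow the caller's keep_dims order
    sorted_keep = sorted(keep_dims)
    if keep_dims != sorted_keep:
        perm = [sorted_keep.index(k) for k in keep_dims]
        mu_r = np.transpose(mu_r, perm)
        sigma_r = np.transpose(sigma_r, perm)
        pts_r = np.transpose(pts_r, perm + [len(perm)])
    return PosteriorField(
        points=pts_r.reshape(-1, len(keep_dims)),
        mu=np.asarray(mu_r).ravel(),
        sigma=np.asarray(sigma_r).ravel(),
    )
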