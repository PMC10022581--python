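"""Torsion-angle conformational spaces.

The ordination pipeline: per-column circular mean-centering of the torsion
table, sin/cos embedding of the wrapped differences (missing angles become
the zero vector), a molecule-by-molecule Pearson correlation matrix computed
over torsions matched in both members of each pair, and SVD of that matrix.
Each molecule's coordinate on axis k is its eigenvector loading scaled by
sqrt(eigenvalue), so the per-axis variance of the embedding equals the
eigenvalue.  Each axis is mapped back to torsion space as a per-torsion
angular delta (the loading-weighted sum of the raw differences), which is
what makes the axes structurally interpretable.

Presented statsmodels-style: :class:`TorsionSpace` is the model,
:meth:`TorsionSpace.fit` returns a :class:`ConformationalSpace` results
object carrying eigenvalues, projections, axis deltas and ``summary()``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TorsionKey, wrap_angle

log = logging.getLogger(__name__)

MIN_MATCHED_KEYS = 3


@dataclass
class DifferenceMatrix:
    """Wrapped angular differences from per-column circular means (degrees)."""

    values: np.ndarray  # molecules x keys, NaN where missing
    columns: list[TorsionKey]
    names: list[str]
    circular_means: np.ndarray

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class EmbeddedDifferences:
    """(sin t, cos t) pairs per torsion; missing angles are exactly (0, 0)."""

    vectors: np.ndarray  # molecules x 2*keys, interleaved (sin, cos)
    present: np.ndarray  # molecules x keys
    columns: list[TorsionKey]
    names: list[str]
    components: int = 2  # embedded components per column


def circular_mean(values: np.ndarray) -> float:
    """Circular mean in degrees of finite entries, via the mean sin/cos vector."""
    finite = values[np.isfinite(values)]
    rad = np.radians(finite)
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def center_differences(table: pd.DataFrame) -> DifferenceMatrix:
    """Subtract each column's circular mean; differences wrapped to (-180, 180]."""
    if len(table) < 2:
        raise ValueError("need at least 2 molecules")
    table = table.dropna(axis=1, how="all")
    raw = table.to_numpy(dtype=float)
    means = np.array([circular_mean(raw[:, j]) for j in range(raw.shape[1])])
    diffs = wrap_angle(raw - means[None, :])
    diffs[~np.isfinite(raw)] = np.nan
    return DifferenceMatrix(
        values=diffs,
        columns=list(table.columns),
        names=list(table.index),
        circular_means=means,
    )


def embed(diff: DifferenceMatrix) -> EmbeddedDifferences:
    """sin/cos embedding of angular differences; missing -> zero vector."""
    rad = np.radians(np.where(diff.present, diff.values, 0.0))
    vectors = np.empty((rad.shape[0], 2 * rad.shape[1]))
    vectors[:, 0::2] = np.sin(rad)
    vectors[:, 1::2] = np.cos(rad)
    absent = np.repeat(~diff.present, 2, axis=1)
    vectors[absent] = 0.0
    return EmbeddedDifferences(
        vectors=vectors,
        present=diff.present.copy(),
        columns=list(diff.columns),
        names=list(diff.names),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx < 1e-300 or sy < 1e-300:
        return np.nan
    return float(np.dot(xc, yc) / (sx * sy))


def correlation_matrix(emb: EmbeddedDifferences) -> np.ndarray:
    """Pairwise Pearson correlation over components matched in both molecules.

    Each embedded component is first centered across the molecules that
    possess it.  Without this the near-constant cosine components (cos t is
    close to 1 for every small difference) saturate every pairwise
    correlation and the leading axis degenerates to a constant vector; after
    per-component centering the correlation reflects only how molecules
    co-vary around the ensemble mean.
    """
    n = emb.vectors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 molecules")
    comp_present = np.repeat(emb.present, emb.components, axis=1)
    counts = comp_present.sum(axis=0)
    sums = np.where(comp_present, emb.vectors, 0.0).sum(axis=0)
    col_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centered = np.where(comp_present, emb.vectors - col_mean[None, :], 0.0)
    corr = np.eye(n)
    if emb.present.all():
        vc = centered - centered.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(vc, axis=1)
        flat = norms < 1e-12
        safe = np.where(flat, 1.0, norms)
        corr = (vc @ vc.T) / np.outer(safe, safe)
        # a zero-variance molecule sits exactly at the ensemble mean; two such
        # molecules are indistinguishable, hence perfectly correlated
        corr[np.ix_(flat, ~flat)] = 0.0
        corr[np.ix_(~flat, flat)] = 0.0
        corr[np.ix_(flat, flat)] = 1.0
        np.fill_diagonal(corr, 1.0)
        return corr
    for i in range(n):
        for j in range(i + 1, n):
            matched = emb.present[i] & emb.present[j]
            if matched.sum() < MIN_MATCHED_KEYS:
                log.warning(
                    "molecules %s and %s share only %d matched torsions; "
                    "correlation set to 0",
                    emb.names[i], emb.names[j], int(matched.sum()),
                )
                r = 0.0
            else:
                sel = comp_present[i] & comp_present[j]
                xi, xj = centered[i, sel], centered[j, sel]
                r = _pearson(xi, xj)
                if not np.isfinite(r):
                    flat_i = np.ptp(xi) < 1e-12
                    flat_j = np.ptp(xj) < 1e-12
                    if flat_i and flat_j:
                        r = 1.0  # both sit at the ensemble mean: identical
                    else:
                        log.warning(
                            "zero-variance matched vector between %s and %s; "
                            "correlation set to 0", emb.names[i], emb.names[j],
                        )
                        r = 0.0
            corr[i, j] = corr[j, i] = r
    return corr


@dataclass
class ConformationalSpace:
    """Results object: the SVD subspace of one ensemble.

    ``projections[m, k]`` is molecule m's coordinate on axis k (eigenvector
    loading scaled by sqrt(eigenvalue)); ``axis_torsion_deltas[k]`` maps each
    torsion identity to the angular change represented by axis k.
    """

    kind: str  # "torsion" | "coordinate"
    names: list[str]
    correlation: np.ndarray
    eigenvalues: np.ndarray  # non-increasing
    loadings: np.ndarray  # molecules x axes (eigenvectors as columns)
    projections: np.ndarray  # molecules x axes, eigenvalue-scaled
    axis_torsion_deltas: list[dict[TorsionKey, float]] | None = None
    columns: list = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.names)

    def projection_frame(self, n_axes: int = 3) -> pd.DataFrame:
        n_axes = min(n_axes, self.projections.shape[1])
        return pd.DataFrame(
            self.projections[:, :n_axes],
            index=self.names,
            columns=[f"axis{k + 1}" for k in range(n_axes)],
        )

    def explained_fraction(self, k: int) -> float:
        pos = np.clip(self.eigenvalues, 0.0, None)
        total = pos.sum()
        return float(pos[k] / total) if total > 0 else 0.0

    def summary(self, n_axes: int = 3) -> str:
        lines = [
            f"Conformational space ({self.kind})",
            f"  molecules: {self.n_molecules}",
            f"  features:  {len(self.columns)}",
            "  axis  eigenvalue  %var(positive)",
        ]
        for k in range(min(n_axes, len(self.eigenvalues))):
            lines.append(
                f"  {k + 1:4d}  {self.eigenvalues[k]:10.4f}"
                f"  {100 * self.explained_fraction(k):8.1f}"
            )
        return "\n".join(lines)

    def to_dict(self, n_axes: int = 3) -> dict:
        n_axes = min(n_axes, self.projections.shape[1])
        return {
            "kind": self.kind,
            "n_axes": n_axes,
            "molecules": list(self.names),
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "projections": {
                name: [float(v) for v in self.projections[i, :n_axes]]
                for i, name in enumerate(self.names)
            },
        }

    def to_json(self, path=None, n_axes: int = 3) -> str:
        text = json.dumps(self.to_dict(n_axes=n_axes), sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path, n_axes: int = 3) -> None:
        self.projection_frame(n_axes).to_csv(path, sep="\t")

    def correlation_tsv(self, path) -> None:
        pd.DataFrame(self.correlation, index=self.names,
                     columns=self.names).to_csv(path, sep="\t")


def svd_space(corr: np.ndarray, emb: EmbeddedDifferences,
              diff: DifferenceMatrix, kind: str = "torsion",
              with_axis_deltas: bool = True) -> ConformationalSpace:
    """Eigendecompose the correlation matrix into a conformational space."""
    if not np.all(np.isfinite(corr)):
        raise ValueError("non-finite correlation entries")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading positive on each axis
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    # numerically-null axes carry arbitrary eigenvectors; give them exactly
    # zero extent instead of sqrt(eps)-sized junk coordinates
    scale = np.sqrt(np.clip(eigvals, 0.0, None))
    if len(eigvals):
        scale[np.abs(eigvals) < 1e-10 * max(np.abs(eigvals).max(), 1.0)] = 0.0
    projections = eigvecs * scale[None, :]
    deltas = None
    if with_axis_deltas and diff is not None:
        deltas = []
        vals = np.where(diff.present, diff.values, 0.0)
        for k in range(eigvecs.shape[1]):
            axis = wrap_angle(eigvecs[:, k] @ vals)
            deltas.append(
                {key: float(axis[j]) for j, key in enumerate(diff.columns)}
            )
    return ConformationalSpace(
        kind=kind,
        names=list(emb.names),
        correlation=corr,
        eigenvalues=eigvals,
        loadings=eigvecs,
        projections=projections,
        axis_torsion_deltas=deltas,
        columns=list(emb.columns),
    )


class TorsionSpace:
    """Model: torsion-angle ordination of a molecules x torsions table."""

    def __init__(self, table: pd.DataFrame):
        if len(table) < 2:
            raise ValueError("need at least 2 molecules")
        self.table = table

    @classmethod
    def from_entity(cls, entity, refined) -> "TorsionSpace":
        from .entity import build_torsion_table

        return cls(build_torsion_table(entity, refined))

    def fit(self) -> ConformationalSpace:
        diff = center_differences(self.table)
        emb = embed(diff)
        corr = correlation_matrix(emb)
        return svd_space(corr, emb, diff, kind="torsion")

    def subset(self, selection: list[str]) -> "TorsionSpace":
        """Model restricted to a molecule subset (full recomputation on fit:
        centering, embedding and correlation are all redone, not projected)."""
        if len(selection) < 2:
            raise ValueError("subset needs at least 2 molecules")
        return TorsionSpace(self.table.loc[list(selection)])


def subset_space(table: pd.DataFrame, selection: list[str]) -> ConformationalSpace:
    """Re-run the whole pipeline on a molecule subset."""
    return TorsionSpace(table).subset(selection).fit()


def procrustes_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two point configurations after optimal
    translation, scaling and rotation (Procrustes alignment)."""
    from scipy.spatial import procrustes

    m1, m2, _ = procrustes(np.asarray(x, float), np.asarray(y, float))
    return float(np.corrcoef(m1.ravel(), m2.ravel())[0, 1])
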