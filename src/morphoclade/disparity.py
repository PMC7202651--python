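"""Morphospace and disparity: MORD distances, PCoA, partial disparity.

Pipeline: pairwise Maximum Observable Rescaled Distances on the (cranial)
character subset → principal coordinates analysis with an optional
negative-eigenvalue correction (Cailliez or Lingoes) → Foote partial
disparity per group over the first ``axis_cap`` axes.

For exclusively unordered characters the per-character MORD dissimilarity
is 0 when the two cells' state sets share a state and 1 otherwise (each
character's observable range is already 1, so no further rescaling is
needed); the pairwise distance is the mean over characters scored in both
OTUs.

Partial disparity follows Foote's convention: PD_g = Σ_{i∈g} Σ_k (x_ik −
c_k)² / (N − 1) with c the grand centroid over all N ordinated OTUs, so
that group contributions add up exactly to total disparity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, GroupMap, MatrixError

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "DisparityTable",
    "mord_matrix",
    "cailliez_correction",
    "lingoes_correction",
    "pcoa",
    "foote_partial_disparity",
    "normalize_partial_disparities",
    "morphospace_table",
    "read_morphospace_table",
]

_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus per-pair comparable-character counts."""

    labels: list[str]
    d: np.ndarray
    comparable_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise MatrixError("distance matrix shape must match labels")
        if not np.allclose(self.d, self.d.T):
            raise MatrixError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise MatrixError("distance matrix must have zero diagonal")

    @property
    def incomputable_pairs(self) -> list[tuple[str, str]]:
        out = []
        if self.comparable_counts is None:
            return out
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.comparable_counts[i, j] == 0:
                    out.append((self.labels[i], self.labels[j]))
        return out


@dataclass
class Ordination:
    """PCoA scores (OTU × axis) and the positive eigenvalues behind them."""

    labels: list[str]
    scores: np.ndarray  # (n, n_positive_axes)
    eigenvalues: np.ndarray  # descending, positive
    correction: str = "none"

    @property
    def n_positive_axes(self) -> int:
        return self.scores.shape[1]

    def variance_explained(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class DisparityTable:
    """Per-group partial disparities, mirroring a published-style table."""

    table: pd.DataFrame  # index: group; columns: pd, pd_percent, pd_per_otu_percent, n_otus
    total: float
    axis_cap: int
    n_otus_total: int

    def __getitem__(self, group: str) -> pd.Series:
        return self.table.loc[group]


# ----------------------------------------------------------------------
def mord_matrix(
    m: CharacterMatrix, partial_overlap_score: float = 0.0
) -> DistanceMatrix:
    """Maximum Observable Rescaled Distance between every pair of OTUs.

    Only characters scored (not missing/inapplicable) in both OTUs are
    compared. A shared state counts as no observable difference by default;
    ``partial_overlap_score`` optionally charges overlapping-but-unequal
    state sets (e.g. 0.5) instead of 0.
    """
    n = m.n_taxa
    if n < 2:
        raise MatrixError("need at least two OTUs")
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    cells = m.cells
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            cnt = 0
            for a, b in zip(cells[i], cells[j]):
                if not (a.is_scored and b.is_scored):
                    continue
                cnt += 1
                if a.states == b.states:
                    pass
                elif a.states & b.states:
                    num += partial_overlap_score
                else:
                    num += 1.0
            counts[i, j] = counts[j, i] = cnt
            d[i, j] = d[j, i] = num / cnt if cnt else 0.0
    dm = DistanceMatrix(labels=list(m.taxon_labels), d=d, comparable_counts=counts)
    if len(dm.incomputable_pairs) == n * (n - 1) // 2:
        raise MatrixError("no pair of OTUs shares a scored character")
    return dm


# ----------------------------------------------------------------------
def _center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _gower(d: np.ndarray) -> np.ndarray:
    return _center(-0.5 * d**2)


def cailliez_correction(dm: DistanceMatrix) -> DistanceMatrix:
    """Add the smallest constant c to off-diagonal distances making the
    configuration Euclidean-embeddable (largest eigenvalue of the standard
    2n × 2n companion problem)."""
    _require_computable(dm)
    d = dm.d
    n = d.shape[0]
    delta1 = _gower(d)
    delta2 = _center(-0.5 * d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = np.linalg.eigvals(np.vstack([upper, lower]))
    c = float(np.max(eigvals.real))
    if c < _TOL:
        c = 0.0
    corrected = d + c
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(
        labels=list(dm.labels), d=corrected, comparable_counts=dm.comparable_counts
    )


def lingoes_correction(dm: DistanceMatrix) -> DistanceMatrix:
    """Add a constant to the squared off-diagonal distances (d' = √(d² + 2c)
    with c = −λ_min of the Gower-centered matrix)."""
    _require_computable(dm)
    d = dm.d
    eigvals = np.linalg.eigvalsh(_gower(d))
    c = float(max(0.0, -eigvals.min()))
    if c < _TOL:
        return DistanceMatrix(
            labels=list(dm.labels), d=d.copy(), comparable_counts=dm.comparable_counts
        )
    corrected = np.sqrt(d**2 + 2.0 * c)
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(
        labels=list(dm.labels), d=corrected, comparable_counts=dm.comparable_counts
    )


def _require_computable(dm: DistanceMatrix) -> None:
    if dm.incomputable_pairs:
        raise MatrixError(
            f"incomputable pairs present: {dm.incomputable_pairs[:3]}..."
        )


# ----------------------------------------------------------------------
def pcoa(dm: DistanceMatrix, correction: str = "none") -> Ordination:
    """Classical metric scaling of a distance matrix.

    Double-center −½D², eigendecompose, keep positive axes, scores =
    eigenvector × √eigenvalue. Per-axis sign is fixed so the first nonzero
    loading is positive.
    """
    if correction == "cailliez":
        dm = cailliez_correction(dm)
    elif correction == "lingoes":
        dm = lingoes_correction(dm)
    elif correction != "none":
        raise ValueError("correction must be none|cailliez|lingoes")
    _require_computable(dm)
    b = _gower(dm.d)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > _TOL * max(1.0, abs(eigvals[0]))
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    scores = eigvecs * np.sqrt(eigvals)
    for k in range(scores.shape[1]):
        col = scores[:, k]
        nz = np.nonzero(np.abs(col) > _TOL)[0]
        if nz.size and col[nz[0]] < 0:
            scores[:, k] = -col
    return Ordination(
        labels=list(dm.labels),
        scores=scores,
        eigenvalues=eigvals,
        correction=correction,
    )


# ----------------------------------------------------------------------
def foote_partial_disparity(
    ordination: Ordination, groups: GroupMap, axis_cap: int = 10
) -> DisparityTable:
    """Partition total disparity over groups (Foote's partial disparity).

    Uses the first ``min(axis_cap, n_positive_axes)`` axes; the grand
    centroid over all N ordinated OTUs is subtracted explicitly and every
    squared distance is divided by N − 1, so Σ_g PD_g equals total
    disparity exactly.
    """
    labels = ordination.labels
    unmapped = [t for t in labels if t not in groups.genus]
    if unmapped:
        raise MatrixError(f"OTUs missing from group map: {unmapped}")
    n = len(labels)
    if n < 2:
        raise MatrixError("need at least two OTUs for disparity")
    cap = min(axis_cap, ordination.n_positive_axes)
    x = ordination.scores[:, :cap]
    centroid = x.mean(axis=0)
    sq = ((x - centroid) ** 2).sum(axis=1) / (n - 1)
    pd_by_group: dict[str, float] = {}
    n_by_group: dict[str, int] = {}
    for label, value in zip(labels, sq):
        g = groups.genus[label]
        pd_by_group[g] = pd_by_group.get(g, 0.0) + float(value)
        n_by_group[g] = n_by_group.get(g, 0) + 1
    return normalize_partial_disparities(pd_by_group, n_by_group, axis_cap=cap)


def normalize_partial_disparities(
    pd_by_group: dict[str, float],
    n_otus_by_group: dict[str, int],
    axis_cap: int = 10,
) -> DisparityTable:
    """Normalization arm: raw per-group PD values → percentage columns.

    Accepts externally supplied PD values (e.g. a published table) as well
    as freshly computed ones; PD% = 100·PD_g/ΣPD and PD/OTU% = PD%/n_g.
    """
    if set(pd_by_group) != set(n_otus_by_group):
        raise MatrixError("PD values and OTU counts must cover the same groups")
    total = float(sum(pd_by_group.values()))
    if total <= 0:
        raise MatrixError("total disparity must be positive")
    rows = []
    for g in pd_by_group:
        pd_g = float(pd_by_group[g])
        n_g = int(n_otus_by_group[g])
        pct = 100.0 * pd_g / total
        rows.append(
            {
                "group": g,
                "pd": pd_g,
                "pd_percent": pct,
                "pd_per_otu_percent": pct / n_g,
                "n_otus": n_g,
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return DisparityTable(
        table=table,
        total=total,
        axis_cap=axis_cap,
        n_otus_total=int(sum(n_otus_by_group.values())),
    )


# ----------------------------------------------------------------------
def morphospace_table(
    ordination: Ordination, groups: GroupMap | None = None, axis_cap: int = 10
) -> str:
    """TSV export of PCoA scores with eigenvalue/variance header rows."""
    cap = min(axis_cap, ordination.n_positive_axes)
    ev = ordination.eigenvalues
    ve = 100.0 * ordination.variance_explained()
    lines = [
        "# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in ev[:cap]),
        "# variance_explained_percent\t" + "\t".join(f"{v:.6f}" for v in ve[:cap]),
        "otu\tgroup\t" + "\t".join(f"PC{k + 1}" for k in range(cap)),
    ]
    for i, label in enumerate(ordination.labels):
        group = groups.genus.get(label, "NA") if groups else "NA"
        row = "\t".join(f"{v:.17g}" for v in ordination.scores[i, :cap])
        lines.append(f"{label}\t{group}\t{row}")
    return "\n".join(lines) + "\n"


def read_morphospace_table(text: str) -> tuple[Ordination, GroupMap | None]:
    """Re-import a :func:`morphospace_table` export (scores and groups)."""
    eigenvalues = None
    labels: list[str] = []
    genus: dict[str, str] = {}
    rows: list[list[float]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("# eigenvalues"):
            eigenvalues = np.array([float(v) for v in line.split("\t")[1:]])
            continue
        if line.startswith("#") or line.startswith("otu\t"):
            continue
        parts = line.split("\t")
        labels.append(parts[0])
        genus[parts[0]] = parts[1]
        rows.append([float(v) for v in parts[2:]])
    scores = np.asarray(rows)
    if eigenvalues is None:
        eigenvalues = (scores**2).sum(axis=0)
    ordination = Ordination(
        labels=labels, scores=scores, eigenvalues=eigenvalues
    )
    gm = None
    if any(g != "NA" for g in genus.values()):
        gm = GroupMap(genus=genus, tribe=dict(genus))
    return ordination, gm
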