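"""Multiple-factor-analysis correlation angles between genes and GI50.

MFA here is run per gene: one variable block holds the gene's data
(expression, optionally with copy number), the other holds the GI50
outcome. Each block's standardized variables are down-weighted by the
block's first singular value so no block dominates, a global SVD is
taken, and every variable is placed on the correlation circle of the
first two global dimensions. The angle between a gene's variable and
the outcome variable summarizes their association: ~0 deg direct
correlation, ~180 deg inverse, ~90 deg none.

With a single expression variable against GI50 the construction
collapses analytically to ``angle = arccos(Pearson r)``, which anchors
the statistic and its tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


class DegenerateVariableError(ValueError):
    """A constant vector has no direction on the correlation circle."""


@dataclass
class AngleRecord:
    """One gene's placement on the correlation circle for one data source."""

    gene: str
    angle: float  # degrees in [0, 180]
    direction: str  # 'direct' (angle <= 90) or 'inverse'
    data_source: str = "GE"  # 'GE', 'CN' or 'GE+CN'
    node_distance: int | None = None  # filled by the pathway module
    parents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError(f"angle {self.angle} outside [0, 180]")
        expected = "direct" if self.angle <= 90.0 else "inverse"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with angle {self.angle}"
            )

    @property
    def folded_angle(self) -> float:
        """Distance (degrees) from the nearer of full direct/inverse correlation."""
        return min(self.angle, 180.0 - self.angle)


def _standardize_columns(block: np.ndarray) -> np.ndarray:
    """Z-score each column and scale to unit norm (so dot products = correlations)."""
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    centered = block - block.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    if np.any(norms == 0.0):
        raise DegenerateVariableError("constant variable in MFA block")
    return centered / norms


def _variable_loadings(groups: list[np.ndarray]) -> np.ndarray:
    """Correlations of every variable with the first two global MFA dimensions.

    Each group's standardized block is divided by its first singular
    value, the scaled blocks are concatenated and decomposed globally;
    with unit-norm variable columns the loading of variable j on
    dimension k is simply its projection on the k-th left singular
    vector, i.e. its correlation with the global scores.
    """
    scaled = []
    standardized = []
    for block in groups:
        z = _standardize_columns(block)
        s1 = np.linalg.svd(z, compute_uv=False)[0]
        standardized.append(z)
        scaled.append(z / s1)
    x = np.hstack(scaled)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    z_all = np.hstack(standardized)
    loadings = z_all.T @ u[:, :2]  # (n_variables, 2)
    return loadings


def angle_between(loadings_a: np.ndarray, loadings_b: np.ndarray) -> float:
    """Angle in degrees between two variables' correlation-circle vectors."""
    na, nb = np.linalg.norm(loadings_a), np.linalg.norm(loadings_b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateVariableError("variable has no projection on the MFA plane")
    cosine = float(np.clip(np.dot(loadings_a, loadings_b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cosine))


def mfa_angle(
    gene_vectors: np.ndarray,
    outcome: np.ndarray,
    gene: str = "",
    data_source: str = "GE",
) -> AngleRecord:
    """Correlation-circle angle of a gene's first variable against the outcome.

    ``gene_vectors`` is an (n_samples,) expression vector or an
    (n_samples, p) block whose first column is expression (e.g. GE+CN).
    All vectors must be non-constant with length >= 3.
    """
    gene_block = np.asarray(gene_vectors, dtype=float)
    if gene_block.ndim == 1:
        gene_block = gene_block[:, None]
    outcome = np.asarray(outcome, dtype=float)
    if gene_block.shape[0] != outcome.shape[0]:
        raise ValueError("gene and outcome vectors differ in length")
    if gene_block.shape[0] < 3:
        raise ValueError("need >=3 samples for an angle")

    if gene_block.shape[1] == 1:
        # two-variable case: exact closed form arccos(Pearson r)
        za = _standardize_columns(gene_block)[:, 0]
        zb = _standardize_columns(outcome)[:, 0]
        cosine = float(np.clip(np.dot(za, zb), -1.0, 1.0))
        angle = math.degrees(math.acos(cosine))
    else:
        loadings = _variable_loadings([gene_block, outcome[:, None]])
        angle = angle_between(loadings[0], loadings[-1])

    direction = "direct" if angle <= 90.0 else "inverse"
    return AngleRecord(gene=gene, angle=angle, direction=direction, data_source=data_source)


def angle_pass(record: AngleRecord | float, theta: float) -> bool:
    """True iff the angle is within theta degrees of full direct (0) or inverse (180)."""
    angle = record.angle if isinstance(record, AngleRecord) else float(record)
    return angle <= theta or angle >= 180.0 - theta


def angle_table(
    matrix: ExpressionMatrix,
    cn: ExpressionMatrix | None,
    gi50: np.ndarray,
    genes: list[str],
) -> tuple[list[AngleRecord], list[tuple[str, str]]]:
    """Score a gene list against GI50; one record per gene per data source.

    Returns (records, skipped) where skipped lists (gene, reason) for
    genes absent from the matrix or with degenerate (constant) data.
    Records are ordered by gene symbol, then data source.
    """
    gi50 = np.asarray(gi50, dtype=float)
    records: list[AngleRecord] = []
    skipped: list[tuple[str, str]] = []
    for gene in sorted(dict.fromkeys(g.upper() for g in genes)):
        ge_vec = matrix.feature_vector(gene) if matrix.has_feature(gene) else None
        cn_vec = (
            cn.feature_vector(gene) if cn is not None and cn.has_feature(gene) else None
        )
        if ge_vec is None and cn_vec is None:
            skipped.append((gene, "absent from expression (and CN) data"))
            continue
        produced = False
        if ge_vec is not None:
            try:
                records.append(mfa_angle(ge_vec, gi50, gene=gene, data_source="GE"))
                produced = True
            except DegenerateVariableError:
                skipped.append((gene, "constant expression vector"))
        if cn_vec is not None:
            try:
                records.append(mfa_angle(cn_vec, gi50, gene=gene, data_source="CN"))
                produced = True
            except DegenerateVariableError:
                skipped.append((gene, "constant copy-number vector"))
        if ge_vec is not None and cn_vec is not None:
            try:
                block = np.column_stack([ge_vec, cn_vec])
                records.append(mfa_angle(block, gi50, gene=gene, data_source="GE+CN"))
                produced = True
            except DegenerateVariableError:
                pass  # already reported above
        if not produced:
            logger.warning("gene %s yielded no angle record", gene)
    records.sort(key=lambda r: (r.gene, r.data_source))
    return records, skipped


def write_angle_table(records: list[AngleRecord], path) -> None:
    """Tab-delimited (gene, source, angle, direction, node_distance, parents)."""
    with open(path, "w") as fh:
        fh.write("gene\tsource\tangle\tdirection\tnode_distance\tparents\n")
        for r in records:
            dist = "" if r.node_distance is None else str(r.node_distance)
            fh.write(
                f"{r.gene}\t{r.data_source}\t{r.angle:.4f}\t{r.direction}\t"
                f"{dist}\t{','.join(r.parents)}\n"
            )


def render_correlation_circle(
    records: list[AngleRecord], outcome_label: str, path
) -> None:
    """Draw the correlation circle: outcome ray at 0 deg, one ray per record."""
    if not records:
        raise ValueError("no records to render")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    circle = plt.Circle((0, 0), 1.0, fill=False, color="grey", lw=0.8)
    ax.add_patch(circle)
    ax.annotate(
        outcome_label,
        xy=(1.0, 0.0),
        xytext=(0.0, 0.0),
        arrowprops=dict(arrowstyle="->", color="black", lw=1.6),
    )
    ax.text(1.02, 0.02, outcome_label, fontsize=9, color="black")
    for r in records:
        rad = math.radians(r.angle)
        x, y = math.cos(rad), math.sin(rad)
        ax.annotate(
            "",
            xy=(x, y),
            xytext=(0.0, 0.0),
            arrowprops=dict(arrowstyle="->", color="tab:blue", lw=0.9),
        )
        ax.text(1.06 * x, 1.06 * y, r.gene, fontsize=7, ha="center", va="center")
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axhline(0, color="grey", lw=0.4)
    ax.axvline(0, color="grey", lw=0.4)
    ax.set_title(f"MFA correlation circle vs {outcome_label}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
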