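"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators emulate the pipeline's real inputs so that every stage
is testable without downloads:

* a cell-line training panel (default 48 lines, the size of a typical
  breast-cancer drug-screening panel) with GI50 drawn over a plausible
  -log10 molar range and a set of planted genes whose expression
  carries an exact in-sample Pearson correlation of ``planted_r`` with
  GI50 (half direct, half inverse), the rest independent noise;
* a toy interaction network with random background edges plus planted
  curated -> one-node -> two-node chains, and an alias table mapping
  fake deprecated symbols onto a fraction of the genes;
* a patient validation cohort with class imbalance, an expression
  shift of ``effect_size`` standard deviations between classes for the
  signature genes (oriented to match each gene's training-panel
  correlation direction), a fraction of genes emitted as duplicate
  probes, and an optional group covariate (e.g. sex) that modulates
  one gene's effect.

All generators are deterministic under a fixed seed. The planted
correlation is exact in-sample (noise is residualized against GI50 and
rescaled) so that a planted gene's correlation angle is analytically
``arccos(planted_r)`` regardless of seed; angle-threshold recovery is
then a property of the pipeline, not of sampling luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    RESISTANT,
    SENSITIVE,
    AliasMap,
    ExpressionMatrix,
    InteractionNetwork,
    ResponseTable,
)

#: baseline log2-scale expression level around which genes fluctuate
_BASELINE = 7.0


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of the toy interaction network."""

    n_extra_nodes: int = 30  # background symbols beyond the expression genes
    edge_density: float = 0.03
    n_chains: int = 4  # planted curated -> 1-node -> 2-node chains
    alias_fraction: float = 0.15


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic fixtures.

    ``planted_r`` is the exact in-sample |Pearson r| between a planted
    gene and GI50; ``effect_size`` the class-mean separation (in SD
    units) of signature genes in the patient cohort; ``imbalance`` the
    resistant fraction of patients.
    """

    n_cell_lines: int = 48
    n_patients: int = 40
    n_genes: int = 120
    n_planted_angle_genes: int = 14
    n_curated: int = 6
    n_cn_correlated: int = 2
    planted_r: float = 0.95
    gi50_range: tuple[float, float] = (3.0, 6.5)
    noise_sd: float = 1.0
    effect_size: float = 2.0
    imbalance: float = 0.75
    probe_dup_fraction: float = 0.3
    network: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.planted_r < 1.0:
            raise ValueError("planted_r must be in (0, 1)")
        if self.n_planted_angle_genes + self.n_cn_correlated > self.n_genes:
            raise ValueError("planted counts exceed n_genes")
        if self.n_curated > self.n_planted_angle_genes:
            raise ValueError("curated genes must be among the planted genes")


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass
class SyntheticPanel:
    """A generated training panel plus its ground truth."""

    expression: ExpressionMatrix
    copy_number: ExpressionMatrix
    responses: ResponseTable
    planted: dict[str, str]  # gene -> 'direct' | 'inverse' (GE-correlated)
    cn_planted: list[str]  # genes whose CN (not GE) tracks GI50
    curated: list[str]
    noise_genes: list[str]


def _planted_vector(
    rng: np.random.Generator, z: np.ndarray, r: float, sign: int
) -> np.ndarray:
    """Unit-variance vector with exact in-sample correlation sign*r to z."""
    e = rng.normal(size=len(z))
    w = e - (e @ z) / (z @ z) * z  # residualize against the outcome
    w_sd = w.std()
    if w_sd == 0.0:
        raise ValueError(f"cannot reach |r|={r}: degenerate noise draw")
    w /= w_sd
    return sign * r * z + np.sqrt(1.0 - r * r) * w


def make_cell_line_panel(spec: SyntheticSpec) -> SyntheticPanel:
    """Expression + copy-number matrices and a GI50 table with planted signal."""
    rng = np.random.default_rng(spec.seed)
    samples = [f"CL{i:02d}" for i in range(1, spec.n_cell_lines + 1)]
    genes = gene_names(spec.n_genes)

    lo, hi = spec.gi50_range
    gi50 = rng.uniform(lo, hi, size=spec.n_cell_lines)
    z = (gi50 - gi50.mean()) / gi50.std()

    planted_genes = genes[: spec.n_planted_angle_genes]
    cn_genes = genes[
        spec.n_planted_angle_genes : spec.n_planted_angle_genes + spec.n_cn_correlated
    ]
    noise_genes = genes[spec.n_planted_angle_genes + spec.n_cn_correlated :]

    expr = np.empty((spec.n_genes, spec.n_cell_lines))
    planted: dict[str, str] = {}
    for i, gene in enumerate(planted_genes):
        sign = 1 if i % 2 == 0 else -1  # half direct, half inverse
        expr[i] = _BASELINE + _planted_vector(rng, z, spec.planted_r, sign)
        planted[gene] = "direct" if sign > 0 else "inverse"
    n_rest = spec.n_genes - spec.n_planted_angle_genes
    expr[spec.n_planted_angle_genes :] = _BASELINE + rng.normal(
        0.0, spec.noise_sd, size=(n_rest, spec.n_cell_lines)
    )

    cn = 2.0 + rng.normal(0.0, 0.3, size=(spec.n_genes, spec.n_cell_lines))
    for gene in cn_genes:
        i = genes.index(gene)
        cn[i] = 2.0 + 0.5 * _planted_vector(rng, z, spec.planted_r, 1)

    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    copy_number = ExpressionMatrix(pd.DataFrame(cn, index=genes, columns=samples))
    responses = ResponseTable(gi50=pd.Series(gi50, index=samples))
    return SyntheticPanel(
        expression=expression,
        copy_number=copy_number,
        responses=responses,
        planted=planted,
        cn_planted=list(cn_genes),
        curated=list(planted_genes[: spec.n_curated]),
        noise_genes=list(noise_genes),
    )


@dataclass
class SyntheticNetwork:
    """A generated interaction network plus its ground truth."""

    network: InteractionNetwork
    aliases: AliasMap
    chains: list[tuple[str, str, str]]  # (curated, one-node, two-node)
    chain_genes: list[str]  # the planted 1- and 2-node genes


def make_network(
    spec: SyntheticSpec,
    curated: list[str],
    planted_paths: list[tuple[str, str, str]] | None = None,
) -> SyntheticNetwork:
    """Random background graph plus deterministic planted chains off the seeds.

    When ``planted_paths`` is omitted, ``spec.network.n_chains`` chains
    curated -> G1 -> G2 are planted, consuming planted-correlated genes
    that are not themselves curated (so the chain genes pass the angle
    filter and recovery is a traversal property).
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = gene_names(spec.n_genes)
    extra = [f"X{i:03d}" for i in range(1, spec.network.n_extra_nodes + 1)]
    nodes = genes + extra

    if planted_paths is None:
        pool = [
            g
            for g in genes[: spec.n_planted_angle_genes]
            if g not in curated
        ]
        n_chains = min(spec.network.n_chains, len(pool) // 2, len(curated))
        planted_paths = [
            (curated[i], pool[2 * i], pool[2 * i + 1]) for i in range(n_chains)
        ]

    chain_nodes = {g for path in planted_paths for g in path}
    edges: list[tuple[str, str, str]] = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a in chain_nodes and b in chain_nodes:
                continue  # background never wires two chain members together
            if rng.random() < spec.network.edge_density:
                edges.append((a, "interacts-with", b))
    for seed_gene, g1, g2 in planted_paths:
        edges.append((seed_gene, "interacts-with", g1))
        edges.append((g1, "interacts-with", g2))

    alias_pairs = []
    for g in nodes:
        if rng.random() < spec.network.alias_fraction:
            alias_pairs.append((f"OLD{g}", g))
    return SyntheticNetwork(
        network=InteractionNetwork.from_edges(edges),
        aliases=AliasMap.from_pairs(alias_pairs),
        chains=list(planted_paths),
        chain_genes=sorted({g for _, g1, g2 in planted_paths for g in (g1, g2)}),
    )


def make_corrupted_associations(
    network: InteractionNetwork, rng: np.random.Generator, n_fake: int = 3
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """A pair list mixing real edges with alias-style spurious links.

    Returns (pairs, fake_pairs): ``pairs`` contains every real edge of
    the network plus ``n_fake`` node pairs that share no edge, the
    latter also returned separately as ground truth.
    """
    real = sorted((a, b) for a, b in network.graph.edges)
    nodes = sorted(network.nodes)
    fakes: list[tuple[str, str]] = []
    attempts = 0
    while len(fakes) < n_fake and attempts < 10_000:
        a, b = rng.choice(nodes, size=2, replace=False)
        if not network.has_edge(a, b) and (a, b) not in fakes:
            fakes.append((str(a), str(b)))
        attempts += 1
    pairs = real + fakes
    return pairs, fakes


@dataclass
class SyntheticCohort:
    """A generated patient validation cohort plus its ground truth."""

    expression: ExpressionMatrix  # probe-level: some genes appear twice
    responses: ResponseTable
    groups: pd.Series  # e.g. sex covariate, 'F'/'M'


def make_patient_cohort(
    spec: SyntheticSpec,
    signature_genes: dict[str, str],
    group_modulated_gene: str | None = None,
) -> SyntheticCohort:
    """Imbalanced two-class cohort with class-shifted signature genes.

    ``signature_genes`` maps gene -> 'direct'/'inverse' (its training
    correlation direction). Sensitive patients sit ``effect_size`` SD
    above resistant ones on direct genes and below on inverse genes, so
    the cohort is separable in the same orientation the training panel
    taught the classifier (higher GI50 on the -log10 scale = sensitive).
    A ``probe_dup_fraction`` of genes is emitted as two probes. When
    ``group_modulated_gene`` is set, that gene's shift is applied only
    in the 'F' group.
    """
    if not signature_genes:
        raise ValueError("signature_genes must be non-empty")
    rng = np.random.default_rng(spec.seed + 2)
    samples = [f"PT{i:03d}" for i in range(1, spec.n_patients + 1)]
    genes = gene_names(spec.n_genes)

    n_resistant = int(round(spec.imbalance * spec.n_patients))
    n_resistant = min(max(n_resistant, 1), spec.n_patients - 1)
    labels = np.array(
        [RESISTANT] * n_resistant + [SENSITIVE] * (spec.n_patients - n_resistant)
    )
    rng.shuffle(labels)
    groups = pd.Series(
        np.where(rng.random(spec.n_patients) < 0.5, "F", "M"), index=samples
    )

    base = _BASELINE + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, spec.n_patients)
    )
    half = spec.effect_size / 2.0
    for gene, direction in signature_genes.items():
        if gene not in genes:
            continue
        i = genes.index(gene)
        shift = np.where(labels == SENSITIVE, half, -half)
        if direction == "inverse":
            shift = -shift
        if gene == group_modulated_gene:
            shift = shift * (groups.to_numpy() == "F")
        base[i] = base[i] + shift

    # emit a fraction of genes as two probes around the gene-level value
    n_dup = int(round(spec.probe_dup_fraction * spec.n_genes))
    dup_idx = sorted(rng.choice(spec.n_genes, size=n_dup, replace=False))
    rows, index = [], []
    for i, gene in enumerate(genes):
        if i in dup_idx:
            for _ in range(2):
                rows.append(base[i] + rng.normal(0.0, 0.15, size=spec.n_patients))
                index.append(gene)
        else:
            rows.append(base[i])
            index.append(gene)
    expression = ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    )
    responses = ResponseTable(label=pd.Series(labels, index=samples, dtype=int))
    return SyntheticCohort(expression=expression, responses=responses, groups=groups)
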