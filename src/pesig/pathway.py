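"""Expansion of a curated gene set through a pathway interaction network.

The curated (distance-0) genes are scored by their MFA correlation
angle against GI50; genes passing the angular threshold recruit their
network neighbours (distance 1), which are scored and filtered the same
way and may in turn recruit distance-2 genes. Genes failing the
threshold are dead ends: expansion never traverses through them. Six
standard conditions pair a maximum node distance {0, 1, 2} with an
angular threshold {10, 20} degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AliasMap, ExpressionMatrix, InteractionNetwork
from .mfa import AngleRecord, angle_pass, angle_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Condition:
    """One preselection condition: how far to expand and how tight the angle filter."""

    id: int | str
    max_depth: int
    theta: float


#: the six standard conditions: depths 0/1/2 crossed with 10/20-degree thresholds
CONDITIONS: dict[int, Condition] = {
    1: Condition(1, 0, 10.0),
    2: Condition(2, 0, 20.0),
    3: Condition(3, 1, 10.0),
    4: Condition(4, 1, 20.0),
    5: Condition(5, 2, 10.0),
    6: Condition(6, 2, 20.0),
}


@dataclass
class GeneEntry:
    """A gene admitted to (or audited out of) a qualified set."""

    gene: str
    node_distance: int
    parents: list[str] = field(default_factory=list)
    records: list[AngleRecord] = field(default_factory=list)  # one per data source
    passed: bool = False
    passing_sources: list[str] = field(default_factory=list)

    @property
    def best_record(self) -> AngleRecord:
        return min(self.records, key=lambda r: r.folded_angle)


@dataclass
class QualifiedGeneSet:
    """Outcome of one expansion run under one condition.

    ``entries`` holds genes that passed the angle filter (keyed by
    symbol, each carrying its minimum node distance and the passing
    parents that recruited it); ``audit`` holds scored-but-failing
    genes; ``skipped`` genes absent from the data.
    """

    condition: Condition
    entries: dict[str, GeneEntry] = field(default_factory=dict)
    audit: dict[str, GeneEntry] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    def svm_feature_pool(self) -> list[str]:
        """Genes whose *expression* passes the filter.

        Genes qualifying only through copy number stay in the set for
        bookkeeping but are excluded here: validation cohorts carry no
        copy-number data, so a CN-only feature could never be scored on
        patients.
        """
        return sorted(
            g for g, e in self.entries.items() if "GE" in e.passing_sources
        )

    def records(self) -> list[AngleRecord]:
        out = []
        for entry in self.entries.values():
            for rec in entry.records:
                rec.node_distance = entry.node_distance
                rec.parents = list(entry.parents)
                out.append(rec)
        out.sort(key=lambda r: (r.node_distance, r.gene, r.data_source))
        return out


def substitute_aliases(
    genes: list[str], aliases: AliasMap
) -> tuple[list[str], dict]:
    """Replace deprecated symbols by their approved names, de-duplicating.

    Returns the substituted list (order of first occurrence preserved)
    and a report with the substitutions applied, symbols not found in
    the map, and duplicates collapsed when two aliases resolve to one
    approved symbol.
    """
    out: list[str] = []
    seen: set[str] = set()
    substitutions: dict[str, str] = {}
    unmapped: list[str] = []
    duplicates: list[str] = []
    for gene in genes:
        approved, known = aliases.resolve(gene)
        if not known:
            unmapped.append(gene.upper())
        elif approved != gene.upper():
            substitutions[gene.upper()] = approved
        if approved in seen:
            duplicates.append(approved)
            continue
        seen.add(approved)
        out.append(approved)
    report = {
        "substitutions": substitutions,
        "unmapped": unmapped,
        "duplicates": duplicates,
    }
    return out, report


def verify_associations(
    pairs: list[tuple[str, str]], network: InteractionNetwork
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Keep only parent-child pairs backed by a network edge.

    Alias mix-ups can attach a gene to the neighbourhood of an
    unrelated symbol that once shared its name; confirming every
    recruited pair against the interaction file removes such spurious
    links. Returns (retained, removed).
    """
    retained, removed = [], []
    for a, b in pairs:
        (retained if network.has_edge(a, b) else removed).append((a.upper(), b.upper()))
    return retained, removed


def _score_layer(
    genes: list[str],
    matrix: ExpressionMatrix,
    cn: ExpressionMatrix | None,
    gi50: np.ndarray,
    theta: float,
) -> tuple[dict[str, GeneEntry], list[tuple[str, str]]]:
    records, skipped = angle_table(matrix, cn, gi50, genes)
    by_gene: dict[str, GeneEntry] = {}
    for rec in records:
        entry = by_gene.setdefault(rec.gene, GeneEntry(gene=rec.gene, node_distance=-1))
        entry.records.append(rec)
        # only the single-source angles decide pass/fail: they equal
        # arccos(Pearson r) exactly, so the null false-pass rate is well
        # controlled; the joint GE+CN placement can exaggerate correlation
        # when both variables project weakly on the 2-D plane and is kept
        # for reporting only
        if rec.data_source in ("GE", "CN") and angle_pass(rec, theta):
            entry.passed = True
            entry.passing_sources.append(rec.data_source)
    return by_gene, skipped


def expand(
    seeds: list[str],
    network: InteractionNetwork,
    matrix: ExpressionMatrix,
    cn: ExpressionMatrix | None,
    gi50: np.ndarray,
    condition: Condition,
    aliases: AliasMap | None = None,
    max_neighbors: int | None = None,
) -> QualifiedGeneSet:
    """Breadth-layered expansion of the curated set under one condition.

    Layer 0 scores the curated genes; layer d <= max_depth scores the
    union of neighbours of *passing* layer-(d-1) genes not already
    assigned a smaller distance. Failing genes are never traversed
    through. ``max_neighbors`` optionally caps how many neighbours a
    single gene may recruit per layer (hub damping; off by default).
    """
    if not seeds:
        raise ValueError("empty curated seed list")
    if aliases is not None:
        seeds, report = substitute_aliases(seeds, aliases)
        if report["substitutions"]:
            logger.info("seed aliases substituted: %s", report["substitutions"])
        network = network.relabel(aliases)
    seeds = [s.upper() for s in seeds]

    result = QualifiedGeneSet(condition=condition)
    gi50 = np.asarray(gi50, dtype=float)

    assigned: set[str] = set()
    layer_genes = list(dict.fromkeys(seeds))
    parent_map: dict[str, list[str]] = {g: [] for g in layer_genes}

    for depth in range(condition.max_depth + 1):
        if not layer_genes:
            break
        scored, skipped = _score_layer(layer_genes, matrix, cn, gi50, condition.theta)
        result.skipped.extend(skipped)
        assigned.update(layer_genes)
        passing_here: list[str] = []
        for gene in sorted(scored):
            entry = scored[gene]
            entry.node_distance = depth
            entry.parents = sorted(parent_map.get(gene, []))
            if entry.passed:
                result.entries[gene] = entry
                passing_here.append(gene)
            else:
                result.audit[gene] = entry
        if depth == 0 and not passing_here:
            logger.warning(
                "no curated gene passes theta=%g; qualified set is empty",
                condition.theta,
            )
            break
        # recruit the next layer from passing genes only
        next_parent_map: dict[str, list[str]] = {}
        for gene in passing_here:
            neighbors = sorted(network.neighbors(gene) - assigned)
            if max_neighbors is not None:
                neighbors = neighbors[:max_neighbors]
            for nb in neighbors:
                next_parent_map.setdefault(nb, []).append(gene)
        layer_genes = sorted(next_parent_map)
        parent_map = next_parent_map

    return result


def run_conditions(
    seeds: list[str],
    network: InteractionNetwork,
    matrix: ExpressionMatrix,
    cn: ExpressionMatrix | None,
    gi50: np.ndarray,
    aliases: AliasMap | None = None,
    max_neighbors: int | None = None,
) -> dict[int, QualifiedGeneSet]:
    """Run all six standard conditions; deterministic output."""
    return {
        cid: expand(seeds, network, matrix, cn, gi50, cond, aliases, max_neighbors)
        for cid, cond in CONDITIONS.items()
    }


def parent_child_pairs(qualified: QualifiedGeneSet) -> list[tuple[str, str]]:
    """All (parent, child) recruitment pairs of a qualified set."""
    pairs = []
    for gene, entry in sorted(qualified.entries.items()):
        for parent in entry.parents:
            pairs.append((parent, gene))
    return pairs


def write_qualified_set(qualified: QualifiedGeneSet, path) -> None:
    """Tab-delimited (gene, node_distance, source, angle, direction, parents)."""
    with open(path, "w") as fh:
        fh.write("gene\tnode_distance\tsource\tangle\tdirection\tparents\n")
        for rec in qualified.records():
            fh.write(
                f"{rec.gene}\t{rec.node_distance}\t{rec.data_source}\t"
                f"{rec.angle:.4f}\t{rec.direction}\t{','.join(rec.parents)}\n"
            )
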