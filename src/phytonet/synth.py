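"""Synthetic benchmark data with known ground truth.

Every pipeline input can be generated here: a compound property table
with an engineered pass/fail split under the default ADME thresholds, a
compound-target edge list with a heavy-tailed degree distribution, a
disease gene set, an annotation collection with planted enriched sets,
and a gene x tissue expression matrix with one planted elevated tissue
per gene.  Defaults are calibrated to the study this pipeline models:
105 candidate compounds of which 30 pass screening, 181 targets hit 5.7
times per compound on average, 97 disease-associated targets, 84 organ
tissues, and property ranges spanning the printed compound table
(OB 16.73-81.61, BBB -0.16-2.17, DL 0.04-0.78).

All randomness flows from the single mandatory seed; each generator
draws from its own derived stream, so datasets are reproducible
independently of generation order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AnnotationCollection,
    CompoundRecord,
    CompoundTable,
    ConfigurationError,
    ExpressionMatrix,
    GeneSet,
    InteractionTable,
    write_compound_table,
    write_expression_matrix,
    write_gene_list,
    write_gmt,
    write_interaction_table,
)
from .adme import AdmeThresholds

import pandas as pd

logger = logging.getLogger("phytonet.synth")

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "gen_compound_table",
    "gen_interactions",
    "gen_disease_set",
    "gen_annotation_collection",
    "gen_expression_matrix",
    "write_bundle",
]

# distinct RNG stream per dataset, all derived from the one seed
_STREAMS = {
    "compounds": 11,
    "interactions": 23,
    "disease": 37,
    "annotation": 53,
    "expression": 71,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    ``pass_fraction`` of the compounds are engineered to satisfy the
    default ADME thresholds; the rest violate at least one.  Interaction
    degrees follow a truncated discrete power law (``degree_exponent``)
    rescaled so the realized edge total equals
    round(``mean_degree`` x active compounds) exactly.
    """

    seed: int
    n_compounds: int = 105
    n_targets: int = 181
    ob_range: tuple[float, float] = (16.73, 81.61)
    bbb_range: tuple[float, float] = (-0.16, 2.17)
    dl_range: tuple[float, float] = (0.04, 0.78)
    pass_fraction: float = 30 / 105
    mean_degree: float = 5.7
    degree_exponent: float = 2.0
    targetless_fraction: float = 2 / 105
    disease_fraction: float = 97 / 181
    n_tissues: int = 84
    unprofiled_fraction: float = 6 / 181
    elevation_factor: float = 5.0
    baseline_log_mean: float = 3.0
    baseline_log_sigma: float = 0.25
    n_annotation_sets: int = 20
    set_size_range: tuple[int, int] = (25, 25)
    planted_sets: int = 1
    planted_overlap: int = 15
    query_size: int = 40

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        for name in ("pass_fraction", "targetless_fraction",
                     "disease_fraction", "unprofiled_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("ob_range", "bbb_range", "dl_range", "set_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} is not ordered: ({lo}, {hi})")
        if self.n_compounds < 1 or self.n_targets < 1:
            raise ConfigurationError("n_compounds and n_targets must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


@dataclass
class GroundTruth:
    """What the generator planted, for verification against its output."""

    passing_compounds: list[str] = field(default_factory=list)
    failing_compounds: list[str] = field(default_factory=list)
    targetless_compounds: list[str] = field(default_factory=list)
    n_edges: int = 0
    target_symbols: list[str] = field(default_factory=list)
    disease_targets: list[str] = field(default_factory=list)
    planted_set_ids: list[str] = field(default_factory=list)
    query_genes: list[str] = field(default_factory=list)
    primary_tissue: dict[str, str] = field(default_factory=dict)
    unprofiled_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        merged = GroundTruth()
        for f in dataclasses.fields(GroundTruth):
            a, b = getattr(self, f.name), getattr(other, f.name)
            setattr(merged, f.name, b if b else a)
        return merged


def _compound_ids(n: int) -> list[str]:
    return [f"M{i}" for i in range(1, n + 1)]


def target_symbols(n: int) -> list[str]:
    """The generator's target/gene universe: T0001 ... T{n}."""
    return [f"T{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Compound table
# ---------------------------------------------------------------------------

def gen_compound_table(cfg: GeneratorConfig) -> tuple[CompoundTable, GroundTruth]:
    """Compound properties with an engineered threshold pass/fail split.

    Exactly round(pass_fraction * n_compounds) records satisfy the
    default thresholds (OB >= 15, BBB >= -0.3, DL >= 0.1); every other
    record violates at least one axis whose sampling range permits a
    violation.  A configuration whose ranges cannot produce the requested
    split is rejected.
    """
    rng = cfg.rng("compounds")
    thr = AdmeThresholds()
    n = cfg.n_compounds
    n_pass = int(round(cfg.pass_fraction * n))

    pass_ranges = {
        "ob": (max(thr.ob_min, cfg.ob_range[0]), cfg.ob_range[1]),
        "bbb": (max(thr.bbb_min, cfg.bbb_range[0]), cfg.bbb_range[1]),
        "dl": (max(thr.dl_min, cfg.dl_range[0]), cfg.dl_range[1]),
    }
    if n_pass > 0:
        for axis, (lo, hi) in pass_ranges.items():
            if lo > hi:
                raise ConfigurationError(
                    f"{axis}_range {getattr(cfg, axis + '_range')} cannot produce "
                    f"threshold-passing values"
                )
    # axes whose range dips below the threshold can carry a violation
    fail_axes = [
        axis
        for axis, (lo, _), cut in (
            ("ob", cfg.ob_range, thr.ob_min),
            ("bbb", cfg.bbb_range, thr.bbb_min),
            ("dl", cfg.dl_range, thr.dl_min),
        )
        if lo < cut
    ]
    if n_pass < n and not fail_axes:
        raise ConfigurationError(
            "pass_fraction < 1 but no property range extends below its threshold"
        )

    ids = _compound_ids(n)
    pass_idx = set(rng.choice(n, size=n_pass, replace=False).tolist())
    # violating values stay one printed digit (0.01) clear of the cut so
    # rounding to 2 decimals cannot flip a record back across a threshold
    margin = 0.01
    cuts = {"ob": thr.ob_min - margin, "bbb": thr.bbb_min - margin,
            "dl": thr.dl_min - margin}
    ranges = {"ob": cfg.ob_range, "bbb": cfg.bbb_range, "dl": cfg.dl_range}
    fail_axes = [a for a in fail_axes if ranges[a][0] < cuts[a]]
    if n_pass < n and not fail_axes:
        raise ConfigurationError(
            "property ranges leave no room below a threshold for failing records"
        )
    records: list[CompoundRecord] = []
    truth = GroundTruth()
    for i, cid in enumerate(ids):
        props: dict[str, float] = {}
        if i in pass_idx:
            for axis, (lo, hi) in pass_ranges.items():
                props[axis] = float(rng.uniform(lo, hi))
            truth.passing_compounds.append(cid)
        else:
            bad = fail_axes[int(rng.integers(len(fail_axes)))]
            for axis in ("ob", "bbb", "dl"):
                lo, hi = ranges[axis]
                if axis == bad:
                    props[axis] = float(rng.uniform(lo, cuts[axis]))
                else:
                    props[axis] = float(rng.uniform(lo, hi))
            truth.failing_compounds.append(cid)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"synthetic compound {i + 1}",
                ob=round(props["ob"], 2),
                bbb=round(props["bbb"], 2),
                dl=round(props["dl"], 2),
            )
        )
    return CompoundTable(records), truth


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

def _power_law_degrees(
    rng: np.random.Generator, n: int, k_max: int, exponent: float, total: int
) -> np.ndarray:
    """n degrees in [1, k_max] summing exactly to ``total``.

    Draws from a truncated discrete power law p(k) proportional to
    k**-exponent, then rescales and repairs the sum one unit at a time.
    """
    ks = np.arange(1, k_max + 1)
    p = ks.astype(float) ** -exponent
    p /= p.sum()
    deg = rng.choice(ks, size=n, p=p)
    scale = total / deg.sum()
    deg = np.clip(np.rint(deg * scale).astype(int), 1, k_max)
    diff = total - int(deg.sum())
    order = rng.permutation(n)
    j = 0
    while diff != 0:
        i = order[j % n]
        if diff > 0 and deg[i] < k_max:
            deg[i] += 1
            diff -= 1
        elif diff < 0 and deg[i] > 1:
            deg[i] -= 1
            diff += 1
        j += 1
        if j > 100 * n + 100:  # pragma: no cover - requires pathological bounds
            raise ConfigurationError("cannot repair degree sequence to edge total")
    return deg


def gen_interactions(
    cfg: GeneratorConfig, compounds: CompoundTable
) -> tuple[InteractionTable, GroundTruth]:
    """Heavy-tailed compound-target edge list covering every target.

    A ``targetless_fraction`` of compounds get no rows; the rest receive
    power-law degrees rescaled so the total edge count equals
    round(mean_degree x active compounds); every target symbol appears in
    at least one edge (repaired by degree-preserving swaps if sampling
    misses some).
    """
    if len(compounds) == 0:
        raise ConfigurationError("compound table is empty")
    rng = cfg.rng("interactions")
    ids = compounds.ids
    n = len(ids)
    n_targetless = int(round(cfg.targetless_fraction * n))
    targetless = set(
        np.array(ids)[rng.choice(n, size=n_targetless, replace=False)].tolist()
    )
    active = [cid for cid in ids if cid not in targetless]
    truth = GroundTruth(
        targetless_compounds=[cid for cid in ids if cid in targetless],
        target_symbols=target_symbols(cfg.n_targets),
    )
    if not active:
        truth.n_edges = 0
        return InteractionTable([]), truth

    total = int(round(cfg.mean_degree * len(active)))
    if total < cfg.n_targets:
        raise ConfigurationError(
            f"cannot cover {cfg.n_targets} targets with only {total} edges; "
            f"raise mean_degree or lower n_targets"
        )
    if total > len(active) * cfg.n_targets:
        raise ConfigurationError("mean_degree exceeds the number of targets")

    symbols = np.array(truth.target_symbols)
    deg = _power_law_degrees(rng, len(active), cfg.n_targets, cfg.degree_exponent, total)
    chosen: dict[str, set[str]] = {}
    for cid, d in zip(active, deg):
        chosen[cid] = set(rng.choice(symbols, size=int(d), replace=False).tolist())

    # repair coverage: swap a duplicated target for each uncovered one
    multiplicity: dict[str, int] = {s: 0 for s in symbols}
    for members in chosen.values():
        for t in members:
            multiplicity[t] += 1
    uncovered = [s for s in symbols if multiplicity[s] == 0]
    for u in uncovered:
        donors = sorted(t for t, c in multiplicity.items() if c >= 2)
        placed = False
        for t_dup in rng.permutation(donors):
            hosts = [cid for cid in active if t_dup in chosen[cid] and u not in chosen[cid]]
            if hosts:
                host = hosts[int(rng.integers(len(hosts)))]
                chosen[host].remove(t_dup)
                chosen[host].add(u)
                multiplicity[t_dup] -= 1
                multiplicity[u] += 1
                placed = True
                break
        if not placed:  # pragma: no cover - impossible while total >= n_targets
            raise ConfigurationError(f"could not place target {u} in any compound")

    edges = [
        (cid, t) for cid in active for t in sorted(chosen[cid])
    ]
    truth.n_edges = len(edges)
    table = InteractionTable(edges)
    logger.info(
        "generated %d edges over %d active compounds (mean %.2f)",
        len(table), len(active), len(table) / len(active),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Disease set, annotation collection, expression matrix
# ---------------------------------------------------------------------------

def gen_disease_set(
    cfg: GeneratorConfig, targets: list[str] | None = None
) -> tuple[GeneSet, GroundTruth]:
    """A disease gene set covering ``disease_fraction`` of the targets."""
    rng = cfg.rng("disease")
    universe = sorted(targets) if targets is not None else target_symbols(cfg.n_targets)
    k = int(round(cfg.disease_fraction * len(universe)))
    if k == 0:
        raise ConfigurationError("disease_fraction selects no targets")
    members = sorted(
        np.array(universe)[rng.choice(len(universe), size=k, replace=False)].tolist()
    )
    truth = GroundTruth(disease_targets=members)
    return GeneSet("disease", frozenset(members)), truth


def gen_annotation_collection(
    cfg: GeneratorConfig, background: GeneSet
) -> tuple[AnnotationCollection, GeneSet, GroundTruth]:
    """Annotation sets over ``background`` with planted enrichment.

    ``planted_sets`` of the ``n_annotation_sets`` sets each contribute
    ``planted_overlap`` members to the emitted query gene set; the rest
    of the query is drawn uniformly from the remaining background.
    """
    if len(background.genes) < 50:
        raise ConfigurationError("annotation background needs >= 50 genes")
    rng = cfg.rng("annotation")
    bg = np.array(sorted(background.genes))
    lo, hi = cfg.set_size_range
    if hi > len(bg):
        raise ConfigurationError("set_size_range exceeds the background size")

    n_sets = cfg.n_annotation_sets
    ids = [f"S{i:03d}" for i in range(1, n_sets + 1)]
    sizes = rng.integers(lo, hi + 1, size=n_sets)
    sets: dict[str, GeneSet] = {}
    for sid, size in zip(ids, sizes):
        members = rng.choice(bg, size=int(size), replace=False)
        sets[sid] = GeneSet(sid, frozenset(members.tolist()), description="synthetic")

    planted = sorted(
        np.array(ids)[rng.choice(n_sets, size=cfg.planted_sets, replace=False)].tolist()
    ) if cfg.planted_sets else []
    query: set[str] = set()
    for sid in planted:
        members = np.array(sorted(sets[sid].genes))
        if cfg.planted_overlap > len(members):
            raise ConfigurationError(
                f"planted_overlap {cfg.planted_overlap} exceeds set size {len(members)}"
            )
        query |= set(
            members[rng.choice(len(members), size=cfg.planted_overlap, replace=False)]
            .tolist()
        )
    if len(query) > cfg.query_size:
        raise ConfigurationError("planted query genes exceed query_size")
    remaining = np.array(sorted(set(bg.tolist()) - query))
    extra = rng.choice(
        remaining, size=cfg.query_size - len(query), replace=False
    )
    query |= set(extra.tolist())

    collection = AnnotationCollection(sets=sets, background=background)
    truth = GroundTruth(planted_set_ids=planted, query_genes=sorted(query))
    return collection, GeneSet("query", frozenset(query)), truth


def gen_expression_matrix(
    cfg: GeneratorConfig, genes: list[str]
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log-normal expression with one planted elevated tissue per gene.

    Baseline values are log-normal with a deliberately tight dispersion
    (``baseline_log_sigma``), so that multiplying one tissue's value by
    ``elevation_factor`` (> 2 required) reliably makes it the gene's
    maximum; ``unprofiled_fraction`` of the genes are omitted from the
    matrix to emulate probes missing from the expression platform.
    """
    if not genes:
        raise ConfigurationError("gene list is empty")
    if cfg.n_tissues < 2:
        raise ConfigurationError("need at least 2 tissues")
    if cfg.elevation_factor <= 2:
        raise ConfigurationError("elevation_factor must exceed 2")
    rng = cfg.rng("expression")
    genes = sorted(set(genes))
    n_omit = int(round(cfg.unprofiled_fraction * len(genes)))
    omit = set(
        np.array(genes)[rng.choice(len(genes), size=n_omit, replace=False)].tolist()
    )
    profiled = [g for g in genes if g not in omit]
    tissues = [f"tissue_{i:02d}" for i in range(1, cfg.n_tissues + 1)]
    values = rng.lognormal(
        mean=cfg.baseline_log_mean,
        sigma=cfg.baseline_log_sigma,
        size=(len(profiled), cfg.n_tissues),
    )
    planted_idx = rng.integers(cfg.n_tissues, size=len(profiled))
    truth = GroundTruth(unprofiled_genes=sorted(omit))
    for i, g in enumerate(profiled):
        values[i, planted_idx[i]] *= cfg.elevation_factor
        truth.primary_tissue[g] = tissues[planted_idx[i]]
    df = pd.DataFrame(values, index=profiled, columns=tissues)
    return ExpressionMatrix(df), truth


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def write_bundle(cfg: GeneratorConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write every pipeline input plus truth.json.

    Emits compounds.tsv, interactions.tsv, disease.txt, annotation.gmt,
    expression.tsv and truth.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, t1 = gen_compound_table(cfg)
    interactions, t2 = gen_interactions(cfg, compounds)
    disease, t3 = gen_disease_set(cfg)
    collection, _query, t4 = gen_annotation_collection(
        cfg, GeneSet("background", frozenset(t2.target_symbols))
    )
    expr, t5 = gen_expression_matrix(cfg, t2.target_symbols)

    write_compound_table(compounds, outdir / "compounds.tsv")
    write_interaction_table(interactions, outdir / "interactions.tsv")
    write_gene_list(disease.genes, outdir / "disease.txt")
    write_gmt(collection, outdir / "annotation.gmt")
    write_expression_matrix(expr, outdir / "expression.tsv")

    truth = t1.merge(t2).merge(t3).merge(t4).merge(t5)
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
    return truth
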