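"""End-to-end alignment strategies.

A strategy names one configuration of the six-step pipeline: gather
pairwise information sources, build the alignment graph, transform its
scores, build a guide tree, align progressively and (optionally) refine
iteratively.  Presets reproduce the commonly compared configurations so
experiments map one-to-one onto strategy labels like ``basic``,
``triplet_seqan`` or ``tree_bf``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .graph import AlignmentGraph, build_graph
from .io import ProteinSequence, SegmentMatch
from .msa import MSA
from .pairwise import (
    ScoringParams,
    global_align,
    lcs_align,
    local_align_topk,
)
from .progressive import progressive_align
from .refine import RefineConfig, msa_score, refine
from .transform import TransformConfig, apply_transform
from .tree import (
    GuideTree,
    build_tree,
    distances_from_global,
    distances_kmer,
)

logger = logging.getLogger("graphmsa")

SOURCES = ("G", "L", "C", "external")


@dataclass(frozen=True)
class StrategyConfig:
    """One point in the strategy space.

    ``sources``: G = global alignment, L = top-4 local alignments,
    C = longest common subsequence, external = a supplied match library.
    When G is absent the guide-tree distances fall back to k-mer counting.
    """

    sources: tuple[str, ...] = ("G", "L")
    transform: TransformConfig = field(default_factory=TransformConfig)
    tree_method: str = "single"
    refine: RefineConfig | None = None
    params: ScoringParams = field(default_factory=ScoringParams)
    local_k: int = 4
    kmer_k: int = 3

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("at least one information source is required")
        for s in self.sources:
            if s not in SOURCES:
                raise ValueError(f"unknown information source {s!r}")


def strategy_preset(name: str, seed: int = 0) -> StrategyConfig:
    """Named strategy configurations for the standard comparisons."""
    presets = {
        "basic": StrategyConfig(),
        "maxflow": StrategyConfig(transform=TransformConfig(("maxflow",))),
        "triplet_tcoffee": StrategyConfig(
            transform=TransformConfig(("triplet_tcoffee",))
        ),
        "triplet_seqan": StrategyConfig(
            transform=TransformConfig(("triplet_seqan",))
        ),
        "triplet_seqan_x2": StrategyConfig(
            transform=TransformConfig(("triplet_seqan",), iterations=2)
        ),
        "clique": StrategyConfig(transform=TransformConfig(("clique",))),
        "triplet_tcoffee_clique": StrategyConfig(
            transform=TransformConfig(("triplet_tcoffee", "clique"))
        ),
        "maxflow_clique": StrategyConfig(
            transform=TransformConfig(("maxflow", "clique"))
        ),
        "random": StrategyConfig(
            refine=RefineConfig("random", iterations=100, seed=seed)
        ),
        "tree_random": StrategyConfig(
            refine=RefineConfig("tree_random", iterations=100, seed=seed)
        ),
        "tree_bf": StrategyConfig(refine=RefineConfig("tree_bf", seed=seed)),
        "triplet_seqan_tree_bf": StrategyConfig(
            transform=TransformConfig(("triplet_seqan",)),
            refine=RefineConfig("tree_bf", seed=seed),
        ),
    }
    return presets[name]


@dataclass
class StrategyResult:
    msa: MSA
    tree: GuideTree
    graph: AlignmentGraph
    log: dict


def gather_matches(
    sequences: Sequence[ProteinSequence],
    cfg: StrategyConfig,
    external_matches: Sequence[SegmentMatch] = (),
) -> tuple[list[SegmentMatch], dict[frozenset[str], float]]:
    """Step 1: pairwise information sources.

    Returns the pooled segment matches and, when global alignments were
    computed, the pairwise identity fractions (reused for tree distances).
    """
    matches: list[SegmentMatch] = []
    identities: dict[frozenset[str], float] = {}
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            a, b = sequences[i], sequences[j]
            if "G" in cfg.sources:
                res = global_align(a, b, cfg.params)
                matches.extend(res.matches)
                identities[frozenset((a.id, b.id))] = res.identity
            if "L" in cfg.sources:
                matches.extend(local_align_topk(a, b, cfg.params, cfg.local_k).matches)
            if "C" in cfg.sources:
                matches.extend(lcs_align(a, b).matches)
    if "external" in cfg.sources:
        matches.extend(external_matches)
    return matches, identities


def run_strategy(
    sequences: Sequence[ProteinSequence],
    cfg: StrategyConfig,
    external_matches: Sequence[SegmentMatch] = (),
) -> StrategyResult:
    """Execute the full pipeline: sources, graph, transform, tree,
    progressive alignment, refinement."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to align")
    log: dict = {"sources": list(cfg.sources)}
    try:
        matches, identities = gather_matches(sequences, cfg, external_matches)
        log["n_matches"] = len(matches)
    except Exception as exc:
        raise RuntimeError(f"information-source stage failed: {exc}") from exc
    try:
        g = build_graph(sequences, matches, cfg.params)
        log["edges_initial"] = g.n_edges
    except Exception as exc:
        raise RuntimeError(f"graph-initialization stage failed: {exc}") from exc
    try:
        g = apply_transform(g, cfg.transform)
        log["transform"] = list(cfg.transform.combine)
        log["edges_transformed"] = g.n_edges
    except Exception as exc:
        raise RuntimeError(f"score-transformation stage failed: {exc}") from exc
    try:
        if "G" in cfg.sources:
            D = distances_from_global(sequences, cfg.params, identities)
            log["distances"] = "global-identity"
        else:
            D = distances_kmer(sequences, cfg.kmer_k)
            log["distances"] = f"{cfg.kmer_k}-mer"
        tree = build_tree(D, cfg.tree_method)
        log["tree_method"] = cfg.tree_method
    except Exception as exc:
        raise RuntimeError(f"guide-tree stage failed: {exc}") from exc
    try:
        msa = progressive_align(g, tree)
        log["score_progressive"] = msa_score(g, msa)
    except Exception as exc:
        raise RuntimeError(f"progressive-alignment stage failed: {exc}") from exc
    if cfg.refine is not None:
        try:
            msa = refine(g, msa, tree, cfg.refine)
            log["refine"] = cfg.refine.strategy
            log["score_refined"] = msa_score(g, msa)
        except Exception as exc:
            raise RuntimeError(f"refinement stage failed: {exc}") from exc
    msa.check_invariants({s.id: s.residues for s in sequences})
    logger.info("strategy log: %s", log)
    return StrategyResult(msa=msa, tree=tree, graph=g, log=log)
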