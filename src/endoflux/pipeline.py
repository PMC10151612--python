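"""Survey orchestration: batched sampling of random host-endosymbiont pairs
from a harmonized collection, aggregation into summary statistics, and
cross-collection comparison.

All randomness flows from a single root seed through named substreams
(sampling / repair restarts / generation), so a survey with a fixed seed on
a fixed collection reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .competition import (
    classify_scenario,
    community_growth,
    pairwise_relative_fitness,
    survival_screen,
)
from .core import MetabolicModel, ModelError
from .endosymbiosis import (
    ConfigurationOutcome,
    EndosymbiosisModel,
    assess_configurations,
    build_pair,
    maximize_pair_growth,
)
from .evolvability import compare_evolvability, tighten_all_bounds
from .fba import VIABILITY_TOLERANCE, maximize_growth
from .stats import AnovaResult, SignRankResult, one_way_anova, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

#: Fixed spawn order of the named substreams off the root seed.
SUBSTREAMS = ("sampling", "repair", "generator")

_CSV_KWARGS = dict(index=False, float_format="%.12g", lineterminator="\n")


@dataclass
class BatchDesign:
    """Sampling plan: ``n_batches`` batches of ``batch_size`` pairs each,
    sampled with replacement over unordered model pairs (both directed
    configurations are evaluated per sampled pair; a model is never paired
    with the same instance of itself)."""

    batch_size: int = 1000
    n_batches: int = 100
    seed: int = 0

    @property
    def n_pairs(self) -> int:
        return self.batch_size * self.n_batches

    def substream(self, name: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(SUBSTREAMS))
        return np.random.default_rng(children[SUBSTREAMS.index(name)])


@dataclass
class SummaryStats:
    """Aggregated output of one survey over one collection."""

    collection_tag: str
    kind: str
    seed: int
    n_pairs: int
    records: pd.DataFrame
    per_batch_viable_fraction: List[float] = field(default_factory=list)
    mean_viable_fraction: Optional[float] = None
    std_viable_fraction: Optional[float] = None
    config_class_fractions: Dict[str, float] = field(default_factory=dict)
    scenario_frequencies: Dict[str, float] = field(default_factory=dict)
    competition_fractions: Dict[str, float] = field(default_factory=dict)
    community_fractions: Dict[str, float] = field(default_factory=dict)
    n_community_excluded: int = 0
    evolvability_summary: Dict[str, float] = field(default_factory=dict)
    signrank_host: Optional[SignRankResult] = None
    signrank_endo: Optional[SignRankResult] = None
    tightened: bool = False

    def summary_dict(self) -> Dict:
        out: Dict = {
            "schema_version": 1,
            "collection_tag": self.collection_tag,
            "kind": self.kind,
            "seed": self.seed,
            "substreams": {name: i for i, name in enumerate(SUBSTREAMS)},
            "n_pairs": self.n_pairs,
        }
        if self.per_batch_viable_fraction:
            out["per_batch_viable_fraction"] = self.per_batch_viable_fraction
            out["mean_viable_fraction"] = self.mean_viable_fraction
            out["std_viable_fraction"] = self.std_viable_fraction
        for key in (
            "config_class_fractions",
            "scenario_frequencies",
            "competition_fractions",
            "community_fractions",
            "evolvability_summary",
        ):
            if getattr(self, key):
                out[key] = getattr(self, key)
        if self.kind == "competition":
            out["n_community_excluded"] = self.n_community_excluded
        for name, res in (("signrank_host", self.signrank_host),
                          ("signrank_endo", self.signrank_endo)):
            if res is not None:
                out[name] = {
                    "statistic": res.statistic,
                    "n": res.n,
                    "p_value": res.p_value,
                    "exact": res.exact,
                }
        if self.tightened:
            out["tightened"] = True
        return out

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(directory / f"{self.kind}_records.csv", **_CSV_KWARGS)
        (directory / f"{self.kind}_summary.json").write_text(
            json.dumps(self.summary_dict(), indent=1, sort_keys=True) + "\n"
        )


def _sample_unordered_pair(
    rng: np.random.Generator, n_models: int
) -> Tuple[int, int]:
    i = int(rng.integers(n_models))
    j = int(rng.integers(n_models - 1))
    if j >= i:
        j += 1
    return i, j


# ---------------------------------------------------------------------------
# Viability survey
# ---------------------------------------------------------------------------


def run_viability_survey(
    collection: Sequence[MetabolicModel], design: BatchDesign
) -> SummaryStats:
    """Viable fraction of random directed endosymbiosis configurations and
    the dual-configuration class (neither / only one / both) per unordered
    pair, batched to estimate sampling variation."""
    if len(collection) < 2:
        raise ModelError("viability survey needs a collection of >= 2 models")
    rng = design.substream("sampling")
    cache: Dict[Tuple[int, int], ConfigurationOutcome] = {}
    rows = []
    per_batch: List[float] = []
    for batch in range(design.n_batches):
        viable = 0
        for k in range(design.batch_size):
            i, j = _sample_unordered_pair(rng, len(collection))
            key = (min(i, j), max(i, j))
            if key not in cache:
                cache[key] = assess_configurations(collection[key[0]], collection[key[1]])
            out = cache[key]
            ab, ba = (
                (out.pair_ab_viable, out.pair_ba_viable)
                if (i, j) == key
                else (out.pair_ba_viable, out.pair_ab_viable)
            )
            viable += int(ab) + int(ba)
            rows.append(
                {
                    "batch": batch,
                    "sample": k,
                    "model_a": collection[key[0]].id,
                    "model_b": collection[key[1]].id,
                    "viable_ab": out.pair_ab_viable,
                    "viable_ba": out.pair_ba_viable,
                    "growth_ab": out.growth_ab,
                    "growth_ba": out.growth_ba,
                    "pair_class": out.pair_class.value,
                }
            )
        per_batch.append(viable / (2 * design.batch_size))
    records = pd.DataFrame(rows)
    class_counts = records["pair_class"].value_counts()
    n = len(records)
    return SummaryStats(
        collection_tag=collection[0].collection_tag,
        kind="viability",
        seed=design.seed,
        n_pairs=design.n_pairs,
        records=records,
        per_batch_viable_fraction=per_batch,
        mean_viable_fraction=float(np.mean(per_batch)),
        std_viable_fraction=float(np.std(per_batch, ddof=1)) if len(per_batch) > 1 else 0.0,
        config_class_fractions={
            cls: float(class_counts.get(cls, 0)) / n
            for cls in ("neither", "only_one", "both")
        },
    )


# ---------------------------------------------------------------------------
# Competition survey
# ---------------------------------------------------------------------------


def _sample_viable_pairs(
    collection: Sequence[MetabolicModel],
    rng: np.random.Generator,
    n_pairs: int,
    max_attempts_factor: int = 50,
):
    """Yield (host, endo, pair, pair_growth) for viable sampled pairs."""
    found = 0
    attempts = 0
    limit = max_attempts_factor * n_pairs
    while found < n_pairs and attempts < limit:
        attempts += 1
        i, j = _sample_unordered_pair(rng, len(collection))
        pair = build_pair(collection[i], collection[j])
        growth = maximize_pair_growth(pair).growth
        if growth >= VIABILITY_TOLERANCE:
            found += 1
            yield collection[i], collection[j], pair, growth
    if found < n_pairs:
        logger.warning(
            "only %d of %d requested viable pairs found in %d attempts",
            found, n_pairs, attempts,
        )


def run_competition_survey(
    collection: Sequence[MetabolicModel],
    design: BatchDesign,
    n_pairs: Optional[int] = None,
) -> SummaryStats:
    """Survival and growth competition of viable pairs against their
    ancestors: single-compound knockout robustness and scenario frequencies,
    pairwise relative fitness in the joint environment, and the two-step
    shared-environment community growth with the 10% uniqueness filter."""
    if len(collection) < 2:
        raise ModelError("competition survey needs a collection of >= 2 models")
    n_pairs = n_pairs if n_pairs is not None else design.n_pairs
    rng = design.substream("sampling")
    rows = []
    scenario_counts: Dict[str, int] = {}
    n_perturbations = 0
    n_excluded = 0
    for host, endo, pair, pair_growth in _sample_viable_pairs(collection, rng, n_pairs):
        env = pair.joint_env
        host_growth = maximize_growth(host, env).growth
        endo_growth = maximize_growth(endo, env).growth
        if (
            host_growth < VIABILITY_TOLERANCE
            or endo_growth < VIABILITY_TOLERANCE
        ):
            continue  # ancestors must be viable in the joint environment
        records, scores = survival_screen(pair, host, endo, env)
        for r in records:
            scenario_counts[r.scenario.value] = scenario_counts.get(r.scenario.value, 0) + 1
        n_perturbations += len(records)
        fit_host = pairwise_relative_fitness(pair_growth, host_growth)
        fit_endo = pairwise_relative_fitness(pair_growth, endo_growth)
        comm = community_growth(host, endo, pair, env)
        if not comm.unique:
            n_excluded += 1
        rows.append(
            {
                "host": host.id,
                "endo": endo.id,
                "pair_growth": pair_growth,
                "host_growth": host_growth,
                "endo_growth": endo_growth,
                "robustness_pair": scores["pair"].proportion,
                "robustness_host": scores["host"].proportion,
                "robustness_endo": scores["endo"].proportion,
                "vs_host": fit_host.classification,
                "vs_host_advantage": fit_host.advantage,
                "vs_endo": fit_endo.classification,
                "vs_endo_advantage": fit_endo.advantage,
                "community_z": comm.z,
                "community_unique": comm.unique,
                "community_pair": comm.entity_max["pair"],
                "community_host": comm.entity_max["host"],
                "community_endo": comm.entity_max["endo"],
            }
        )
    records_df = pd.DataFrame(rows)
    n = len(records_df)
    competition_fractions: Dict[str, float] = {}
    community_fractions: Dict[str, float] = {}
    if n:
        for ref in ("host", "endo"):
            col = records_df[f"vs_{ref}"]
            for cls in ("slower", "faster", "equal"):
                competition_fractions[f"pair_{cls}_than_{ref}"] = float(
                    (col == cls).sum()
                ) / n
        competition_fractions["pair_slower_than_both"] = float(
            ((records_df["vs_host"] == "slower") & (records_df["vs_endo"] == "slower")).sum()
        ) / n
        uniq = records_df[records_df["community_unique"]]
        if len(uniq):
            tol = 1e-9
            slower_both = (
                (uniq["community_pair"] < uniq["community_host"] - tol)
                & (uniq["community_pair"] < uniq["community_endo"] - tol)
            )
            faster_host = uniq["community_pair"] > uniq["community_host"] + tol
            faster_endo = uniq["community_pair"] > uniq["community_endo"] + tol
            m = len(uniq)
            community_fractions = {
                "pair_slower_than_both": float(slower_both.sum()) / m,
                "pair_faster_than_host": float(faster_host.sum()) / m,
                "pair_faster_than_endo": float(faster_endo.sum()) / m,
            }
    total_scen = sum(scenario_counts.values())
    return SummaryStats(
        collection_tag=collection[0].collection_tag,
        kind="competition",
        seed=design.seed,
        n_pairs=n,
        records=records_df,
        scenario_frequencies={
            k: v / total_scen for k, v in sorted(scenario_counts.items())
        }
        if total_scen
        else {},
        competition_fractions=competition_fractions,
        community_fractions=community_fractions,
        n_community_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Evolvability survey
# ---------------------------------------------------------------------------


def run_evolvability_survey(
    collection: Sequence[MetabolicModel],
    design: BatchDesign,
    n_pairs: Optional[int] = None,
    _tightened: bool = False,
) -> SummaryStats:
    """Mutation scans over viable pairs that grow more slowly than both
    ancestors, compared context by context with the ancestral scans.

    If the collection turns out bound-insensitive (no beneficial mutation in
    any context of any sampled pair), all reaction bounds are tightened by a
    factor of 100 and the survey re-run once, mirroring the treatment of
    collections whose growth is limited by the environment alone."""
    if len(collection) < 2:
        raise ModelError("evolvability survey needs a collection of >= 2 models")
    n_pairs = n_pairs if n_pairs is not None else design.n_pairs
    rng = design.substream("sampling")
    rows = []
    diffs_host: List[float] = []
    diffs_endo: List[float] = []
    pooled = {"pair_beneficial": 0, "exceed_host": 0, "exceed_endo": 0}
    n_pair_max_exceeds = 0
    for host, endo, pair, pair_growth in _sample_viable_pairs(collection, rng, n_pairs):
        env = pair.joint_env
        host_growth = maximize_growth(host, env).growth
        endo_growth = maximize_growth(endo, env).growth
        if not (pair_growth < host_growth and pair_growth < endo_growth):
            continue  # survey restricted to slower-than-both-ancestors pairs
        comp = compare_evolvability(pair, host, endo, env)
        diffs_host.append(
            comp.n_beneficial["ancestral_host"] - comp.n_beneficial["pair_host_reaction"]
        )
        diffs_endo.append(
            comp.n_beneficial["ancestral_endo"] - comp.n_beneficial["pair_endo_reaction"]
        )
        for ctx, flag in (
            ("pair_host_reaction", "exceed_host"),
            ("pair_endo_reaction", "exceed_endo"),
        ):
            for e in comp.effects[ctx]:
                if e.beneficial:
                    pooled["pair_beneficial"] += 1
                    if flag == "exceed_host" and e.exceeds_host_ancestor:
                        pooled["exceed_host"] += 1
                    if flag == "exceed_endo" and e.exceeds_endo_ancestor:
                        pooled["exceed_endo"] += 1
        pair_max = max(
            comp.max_growth_reached["pair_host_reaction"],
            comp.max_growth_reached["pair_endo_reaction"],
        )
        ancestor_max = max(
            comp.max_growth_reached["ancestral_host"],
            comp.max_growth_reached["ancestral_endo"],
        )
        if pair_max > ancestor_max * (1 + 1e-9):
            n_pair_max_exceeds += 1
        rows.append(
            {
                "host": host.id,
                "endo": endo.id,
                "pair_growth": pair_growth,
                "host_growth": host_growth,
                "endo_growth": endo_growth,
                "beneficial_ancestral_host": comp.n_beneficial["ancestral_host"],
                "beneficial_ancestral_endo": comp.n_beneficial["ancestral_endo"],
                "beneficial_pair_host": comp.n_beneficial["pair_host_reaction"],
                "beneficial_pair_endo": comp.n_beneficial["pair_endo_reaction"],
                "pair_max_growth": pair_max,
                "ancestor_max_growth": ancestor_max,
            }
        )
    records_df = pd.DataFrame(rows)
    total_beneficial = (
        int(
            records_df[
                [
                    "beneficial_ancestral_host",
                    "beneficial_ancestral_endo",
                    "beneficial_pair_host",
                    "beneficial_pair_endo",
                ]
            ].to_numpy().sum()
        )
        if len(records_df)
        else 0
    )
    if total_beneficial == 0 and not _tightened and len(records_df):
        logger.info("no beneficial mutations found; tightening bounds by 100x")
        tightened = [tighten_all_bounds(m, 100.0) for m in collection]
        stats = run_evolvability_survey(tightened, design, n_pairs, _tightened=True)
        stats.tightened = True
        return stats
    summary: Dict[str, float] = {
        "n_pairs_scanned": float(len(records_df)),
        "n_pair_max_exceeds_ancestors": float(n_pair_max_exceeds),
    }
    if pooled["pair_beneficial"]:
        summary["frac_beneficial_exceed_host"] = (
            pooled["exceed_host"] / pooled["pair_beneficial"]
        )
        summary["frac_beneficial_exceed_endo"] = (
            pooled["exceed_endo"] / pooled["pair_beneficial"]
        )
    return SummaryStats(
        collection_tag=collection[0].collection_tag,
        kind="evolvability",
        seed=design.seed,
        n_pairs=len(records_df),
        records=records_df,
        evolvability_summary=summary,
        signrank_host=wilcoxon_signed_rank(diffs_host) if diffs_host else None,
        signrank_endo=wilcoxon_signed_rank(diffs_endo) if diffs_endo else None,
        tightened=_tightened,
    )


# ---------------------------------------------------------------------------
# Cross-collection comparison
# ---------------------------------------------------------------------------


def summarize_across_collections(stats: Sequence[SummaryStats]) -> AnovaResult:
    """One-way ANOVA over per-batch viable fractions of several collections."""
    groups = []
    for s in stats:
        if len(s.per_batch_viable_fraction) < 2:
            logger.warning(
                "collection %s has < 2 batches; excluded from ANOVA", s.collection_tag
            )
            continue
        groups.append(s.per_batch_viable_fraction)
    if len(groups) < 2:
        raise ModelError("cross-collection comparison needs >= 2 collections "
                         "with >= 2 batches each")
    return one_way_anova(groups)
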