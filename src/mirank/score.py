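"""Total-score computation and ranking of candidate miRNAs.

For each miRNA, a per-gene interaction score is the sum of its standardized
evaluations across all databases for that gene (0 when no database lists
the pair).  Summing over the configured target genes yields the overall
interaction score, bounded by 39 under the default five-database, six-gene
setup (two binary databases contribute at most 1 each, three offset
databases at most 1.5 each: 6.5 per gene × 6 genes).

The expression component sums a miRNA's normalized (variance-stabilized,
non-negative) expression over the configured brain regions and multiplies
by the expression factor, 2.4 by default (0.4 per target gene), so that
the two components carry comparable weight.  The total score is the exact
sum of the two components; miRNAs are ranked by descending total score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger("mirank")

DEFAULT_TARGET_GENES = ("BDNF", "HTR1A", "SLC6A4", "NR3C1", "ZNF714", "NRIP3")
DEFAULT_REGIONS = ("brain_1", "brain_cerebral_coretex_2")


class ScoreError(ValueError):
    """Fatal scoring problem: contract violation in the inputs."""


@dataclass(frozen=True)
class ScoringConfig:
    target_genes: tuple[str, ...] = DEFAULT_TARGET_GENES
    expression_regions: tuple[str, ...] = DEFAULT_REGIONS
    per_gene_weight: float = 0.4
    expression_factor: float | None = None  # derived when None
    expression_combine: str = "sum"  # "sum" | "mean"
    top_k: int = 10

    def __post_init__(self):
        if not self.target_genes:
            raise ScoreError("target_genes must be non-empty")
        if len(set(self.target_genes)) != len(self.target_genes):
            raise ScoreError("target_genes must be unique")
        if self.expression_combine not in ("sum", "mean"):
            raise ScoreError("expression_combine must be 'sum' or 'mean'")

    @property
    def effective_expression_factor(self) -> float:
        if self.expression_factor is not None:
            return self.expression_factor
        return self.per_gene_weight * len(self.target_genes)


def load_scoring_config(path) -> ScoringConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("target_genes", "expression_regions"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ScoringConfig(**raw)


# ---------------------------------------------------------------------------
# score components

def gene_interaction_score(evaluations, databases=None) -> float:
    """Sum a miRNA's evaluations for one gene across databases.

    ``databases``, when given, must hold at most one entry per database —
    two records from one source means deduplication was skipped upstream.
    """
    evaluations = list(evaluations)
    if databases is not None:
        databases = list(databases)
        if len(set(databases)) != len(databases):
            raise ScoreError("multiple records from one database for one "
                             "(miRNA, gene) pair — deduplicate first")
    return float(sum(evaluations))


def overall_interaction_score(gene_scores: dict[str, float],
                              config: ScoringConfig) -> float:
    """Sum per-gene scores over the configured genes (missing genes → 0)."""
    unknown = set(gene_scores) - set(config.target_genes)
    if unknown:
        raise ScoreError(f"gene(s) outside the configured target set: "
                         f"{sorted(unknown)}")
    return float(sum(gene_scores.get(g, 0.0) for g in config.target_genes))


def expression_score(region_values: dict[str, float],
                     config: ScoringConfig) -> tuple[float, float]:
    """Combine per-region expression into (raw, weighted) components.

    Regions absent from the profile count 0 with a warning; negative values
    violate the corrected non-negative scale contract and are fatal.
    """
    values = []
    for region in config.expression_regions:
        value = region_values.get(region)
        if value is None:
            logger.warning("missing expression value for region %r; using 0",
                           region)
            value = 0.0
        if value < 0:
            raise ScoreError(f"negative expression value {value} in region "
                             f"{region!r}")
        values.append(float(value))
    if config.expression_combine == "mean" and values:
        raw = sum(values) / len(values)
    else:
        raw = sum(values)
    return raw, raw * config.effective_expression_factor


def total_score(interaction: float, expression: float) -> float:
    """Exact sum of the interaction and weighted-expression components."""
    if interaction < 0 or expression < 0:
        raise ScoreError("score components must be non-negative")
    return interaction + expression


# ---------------------------------------------------------------------------
# scorecards

def build_scorecards(records: pd.DataFrame,
                     expression: pd.DataFrame | None,
                     config: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every miRNA in a standardized record table and rank all.

    ``expression`` is a table with a ``mirna_key`` column and one column per
    tissue region; miRNAs absent from it receive an expression score of 0
    (partial data never excludes a candidate).  Returns one row per miRNA
    with per-gene scores, both components, the total score and the rank.
    """
    config = config or ScoringConfig()
    relevant = records[records["gene_symbol"].isin(config.target_genes)]
    dupes = relevant.duplicated(["mirna_key", "gene_symbol", "database_name"])
    if dupes.any():
        raise ScoreError("record table contains duplicate (miRNA, gene, "
                         "database) triples — deduplicate first")

    per_gene = (relevant.groupby(["mirna_key", "gene_symbol"])["evaluation"]
                .sum().unstack(fill_value=0.0))
    mirnas = sorted(set(records["mirna_key"]))
    cards = pd.DataFrame(index=pd.Index(mirnas, name="mirna_key"))
    for gene in config.target_genes:
        cards[gene] = per_gene[gene] if gene in per_gene else 0.0
    cards = cards.fillna(0.0)
    cards["interaction_score"] = cards[list(config.target_genes)].sum(axis=1)

    profiles: dict[str, dict[str, float]] = {}
    if expression is not None and not expression.empty:
        idx = expression.set_index("mirna_key")
        profiles = idx.to_dict(orient="index")
    zeros = {region: 0.0 for region in config.expression_regions}
    raw_scores, weighted = [], []
    n_absent = 0
    for mirna in cards.index:
        profile = profiles.get(mirna)
        if profile is None:  # partial data: absent miRNA scores 0
            profile = zeros
            n_absent += 1
        raw, score = expression_score(profile, config)
        raw_scores.append(raw)
        weighted.append(score)
    if n_absent:
        logger.warning("%d of %d miRNAs absent from the expression table; "
                       "their expression score is 0", n_absent, len(cards))
    cards["expression_raw"] = raw_scores
    cards["expression_score"] = weighted
    cards["total_score"] = cards["interaction_score"] + cards["expression_score"]
    return rank_mirnas(cards.reset_index(), config)


def rank_mirnas(cards: pd.DataFrame, config: ScoringConfig | None = None
                ) -> pd.DataFrame:
    """Order by descending total score and assign ranks 1..N.

    Ties break by higher interaction score, then lexicographic miRNA key,
    so the top-k selection is deterministic.
    """
    out = cards.sort_values(
        by=["total_score", "interaction_score", "mirna_key"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def select_top(cards: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k scorecards by rank; k beyond N returns all with a warning."""
    if k <= 0:
        raise ScoreError(f"top-k must be positive, got {k}")
    if "rank" not in cards.columns:
        raise ScoreError("scorecards must be ranked before selection")
    if k > len(cards):
        logger.warning("requested top %d of %d miRNAs; returning all",
                       k, len(cards))
    return cards.nsmallest(min(k, len(cards)), "rank").sort_values("rank")


def write_scorecards(cards: pd.DataFrame, path) -> None:
    cards.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "mirna_key" not in frame.columns:
        raise ScoreError("expression table must have a 'mirna_key' column")
    return frame
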