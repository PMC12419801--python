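"""Membrane-propensity scoring and nonparametric group comparison.

A protein's membrane propensity is the mean per-residue transmembrane
tendency H = (1/n) Σ h_j over its scored residues, where h_j comes from a
20-residue propensity scale.  Families are summarized by the distribution of
their members' H values, classified transmembrane vs soluble against a
boundary, and compared with the Kruskal–Wallis test followed by Dunn's
post-hoc pairwise z-tests with Bonferroni correction.  Families not separated
by any significant pairwise test are grouped into critical-difference
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

logger = logging.getLogger("superfam.tm")

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = frozenset("XBZUO*")

#: Transmembrane tendency scale of Zhao & London (2006), Protein Science
#: 15:1987-2001.  Positive values favour the bilayer interior; the scale is
#: constructed so that typical soluble sequences average below zero and
#: single-pass TM helices well above it.
ZHAO_LONDON_TM_TENDENCY: dict[str, float] = {
    "A": 0.38, "R": -2.57, "N": -1.62, "D": -3.27, "C": -0.30,
    "Q": -1.84, "E": -2.90, "G": -0.19, "H": -1.44, "I": 1.97,
    "L": 1.82, "K": -3.46, "M": 1.40, "F": 1.98, "P": -1.44,
    "S": -0.53, "T": -0.32, "W": 1.53, "Y": 0.49, "V": 1.46,
}


@dataclass(frozen=True)
class TMScale:
    """Residue → propensity mapping (dimensionless scale units)."""

    values: Mapping[str, float]
    name: str = "custom"
    ambiguity_policy: str = "skip"  # or "error"

    def __post_init__(self) -> None:
        missing = [r for r in CANONICAL_RESIDUES if r not in self.values]
        if missing:
            raise ValidationError(
                f"scale {self.name!r}: missing canonical residue(s) {missing}"
            )
        for res, val in self.values.items():
            if not np.isfinite(val):
                raise ValidationError(f"scale {self.name!r}: non-finite value for {res!r}")
        if self.ambiguity_policy not in ("skip", "error"):
            raise ParameterError(
                f"ambiguity_policy must be 'skip' or 'error', got {self.ambiguity_policy!r}"
            )

    @property
    def min_value(self) -> float:
        return min(self.values[r] for r in CANONICAL_RESIDUES)

    @property
    def max_value(self) -> float:
        return max(self.values[r] for r in CANONICAL_RESIDUES)

    def most_hydrophobic(self) -> str:
        return max(CANONICAL_RESIDUES, key=lambda r: self.values[r])

    def most_hydrophilic(self) -> str:
        return min(CANONICAL_RESIDUES, key=lambda r: self.values[r])


def tm_tendency_scale(ambiguity_policy: str = "skip") -> TMScale:
    """The shipped published TM tendency scale (Zhao & London 2006)."""
    return TMScale(values=dict(ZHAO_LONDON_TM_TENDENCY), name="tm_tendency",
                   ambiguity_policy=ambiguity_policy)


@dataclass(frozen=True)
class SequenceRecord:
    """A family-tagged protein sequence, optionally with core-helix intervals.

    ``core_regions`` are 1-based inclusive (aa_start, aa_end) intervals that
    must be sorted, non-overlapping and within the sequence.
    """

    sequence_id: str
    family_id: str
    residues: str
    core_regions: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 1:
            raise ValidationError(f"sequence {self.sequence_id!r}: empty residues")
        if self.core_regions is not None:
            prev_end = 0
            for start, end in self.core_regions:
                if start < 1 or end > n or end < start:
                    raise ValidationError(
                        f"sequence {self.sequence_id!r}: interval ({start}, {end}) "
                        f"outside [1, {n}] or inverted"
                    )
                if start <= prev_end:
                    raise ValidationError(
                        f"sequence {self.sequence_id!r}: intervals overlap or unsorted"
                    )
                prev_end = end


@dataclass(frozen=True)
class FamilyScoreSet:
    """Per-sequence membrane-propensity scores of one family."""

    family_id: str
    sequence_ids: tuple[str, ...]
    scores: tuple[float, ...]
    full_length: bool = True

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValidationError(f"family {self.family_id!r}: empty score set")
        if len(self.sequence_ids) != len(self.scores):
            raise ValidationError(f"family {self.family_id!r}: id/score length mismatch")


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal–Wallis omnibus plus Dunn pairwise results and CD grouping."""

    H_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # family_a, family_b, z, p_raw, p_adjusted
    alpha: float
    cd_groups: tuple[frozenset[str], ...]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _scored_residues(record: SequenceRecord, use_core: bool) -> str:
    if use_core:
        if record.core_regions is None:
            raise ValidationError(
                f"sequence {record.sequence_id!r}: use_core requested but no "
                "core_regions present"
            )
        return "".join(
            record.residues[s - 1:e] for s, e in record.core_regions
        )
    return record.residues


def sequence_tm_score(record: SequenceRecord, scale: TMScale,
                      use_core: bool = False) -> float:
    """Mean per-residue propensity H = (1/n) Σ h_j over the scored region."""
    region = _scored_residues(record, use_core).upper()
    total = 0.0
    n = 0
    skipped = 0
    for res in region:
        try:
            total += scale.values[res]
        except KeyError:
            if res in AMBIGUOUS_RESIDUES and scale.ambiguity_policy == "skip":
                skipped += 1
                continue
            raise ValidationError(
                f"sequence {record.sequence_id!r}: residue {res!r} absent from "
                f"scale {scale.name!r}"
            ) from None
        n += 1
    if skipped:
        logger.debug("sequence %s: skipped %d ambiguous residue(s)",
                     record.sequence_id, skipped)
    if n == 0:
        raise ValidationError(
            f"sequence {record.sequence_id!r}: no scorable residues in region"
        )
    return total / n


def family_scores(records: Iterable[SequenceRecord], scale: TMScale,
                  use_core: bool = False) -> list[FamilyScoreSet]:
    """Group per-sequence scores by family (sorted by family_id).

    The grouping is order-independent: scores within a family are sorted by
    sequence_id.
    """
    by_family: dict[str, list[tuple[str, float]]] = {}
    for rec in records:
        score = sequence_tm_score(rec, scale, use_core=use_core)
        by_family.setdefault(rec.family_id, []).append((rec.sequence_id, score))
    if not by_family:
        raise ValidationError("no sequence records supplied")
    sets = []
    for family_id in sorted(by_family):
        pairs = sorted(by_family[family_id])
        sets.append(FamilyScoreSet(
            family_id=family_id,
            sequence_ids=tuple(p[0] for p in pairs),
            scores=tuple(p[1] for p in pairs),
            full_length=not use_core,
        ))
    return sets


def scores_frame(score_sets: Sequence[FamilyScoreSet]) -> pd.DataFrame:
    """Tidy per-sequence score table (sequence_id, family_id, tm_score)."""
    rows = [
        (sid, fs.family_id, score)
        for fs in score_sets
        for sid, score in zip(fs.sequence_ids, fs.scores)
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "family_id", "tm_score"])


def classify_families(score_sets: Sequence[FamilyScoreSet],
                      boundary: float = 0.0,
                      statistic: str = "median") -> dict[str, str]:
    """Label each family TM or soluble by its score statistic vs a boundary.

    Ties (statistic exactly equal to the boundary) are labeled soluble and
    logged, so raising the boundary never converts soluble → TM.
    """
    if not np.isfinite(boundary):
        raise ParameterError("boundary must be finite")
    if statistic not in ("median", "mean"):
        raise ParameterError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    stat_fn = np.median if statistic == "median" else np.mean
    labels = {}
    for fs in score_sets:
        value = float(stat_fn(fs.scores))
        if value == boundary:
            logger.info("family %s: statistic exactly at boundary; labeled soluble",
                        fs.family_id)
        labels[fs.family_id] = "TM" if value > boundary else "soluble"
    return labels


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def kruskal_wallis(score_sets: Sequence[FamilyScoreSet]) -> tuple[float, float]:
    """Kruskal–Wallis H on mid-ranks with tie correction; chi² p, k−1 df."""
    if len(score_sets) < 2:
        raise ValidationError("Kruskal-Wallis requires >= 2 groups")
    groups = [np.asarray(fs.scores, dtype=float) for fs in score_sets]
    if sum(g.size for g in groups) < 3:
        raise ValidationError("Kruskal-Wallis requires total N >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValidationError(
            "degenerate data: all values identical across all groups "
            "(tie-correction denominator is zero)"
        )
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def _dunn_tables(score_sets: Sequence[FamilyScoreSet]):
    groups = [np.asarray(fs.scores, dtype=float) for fs in score_sets]
    names = [fs.family_id for fs in score_sets]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        pos += g.size
    # tie correction on the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    variance_base = N * (N + 1) / 12.0 - tie_term
    return names, groups, np.array(mean_ranks), variance_base


def dunn_posthoc(score_sets: Sequence[FamilyScoreSet],
                 alpha: float = 0.05) -> GroupComparison:
    """Dunn's pairwise z-tests with Bonferroni adjustment and CD grouping.

    z for a pair is the mean-rank difference over the tie-corrected pooled
    standard error; p_raw is two-sided normal; p_adjusted = min(1, p_raw ×
    k(k−1)/2).  Families are merged into one critical-difference group when
    joined by any non-significant pair (p_adjusted ≥ alpha).
    """
    if len(score_sets) < 2:
        raise ValidationError("Dunn post-hoc requires >= 2 groups")
    H, p_omnibus = kruskal_wallis(score_sets)
    names, groups, mean_ranks, variance_base = _dunn_tables(score_sets)
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    rows = []
    cd = nx.Graph()
    cd.add_nodes_from(names)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(variance_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p_raw * n_pairs)
            rows.append((names[i], names[j], float(z), float(p_raw), float(p_adj)))
            if p_adj >= alpha:
                cd.add_edge(names[i], names[j])
    pairwise = pd.DataFrame(
        rows, columns=["family_a", "family_b", "z", "p_raw", "p_adjusted"]
    )
    components = tuple(sorted(
        (frozenset(c) for c in nx.connected_components(cd)),
        key=lambda c: sorted(c),
    ))
    return GroupComparison(H_statistic=H, p_value=p_omnibus, pairwise=pairwise,
                           alpha=alpha, cd_groups=components)


def cd_groups_frame(comparison: GroupComparison) -> pd.DataFrame:
    """Tidy critical-difference grouping table (family_id, cd_group)."""
    rows = [
        (family, idx)
        for idx, component in enumerate(comparison.cd_groups)
        for family in sorted(component)
    ]
    return pd.DataFrame(rows, columns=["family_id", "cd_group"])
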