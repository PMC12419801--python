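"""Phyletic spread and depth metrics for clades over lineage samples.

For clade *i* observed across *M* lineages, with ``n_j`` species of lineage
*j* carrying at least one member and ``N_j`` species sampled in lineage *j*:

* spread  ``S_i = m_i / M`` where ``m_i = |{j : n_j > 0}|`` — the fraction of
  lineages with any representative;
* depth   ``D_i = Σ n_j / Σ N_j`` — the mediant of the per-lineage occupancy
  fractions, summed over all M lineages including absent ones.

Both lie in [0, 1]; the mediant always lies between the extreme per-lineage
fractions.  Presence counts species (paralogs in one species do not inflate
``n_j``).  The bar-graph encoding plots each clade as a bar of width S and
height D.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class LineageCount:
    lineage_id: str
    n_present: int  # species with >= 1 representative (n_j)
    n_sampled: int  # species sampled in the lineage (N_j)

    def __post_init__(self) -> None:
        if self.n_sampled < 1:
            raise ValidationError(
                f"lineage {self.lineage_id!r}: N_j must be >= 1, got {self.n_sampled}"
            )
        if not 0 <= self.n_present <= self.n_sampled:
            raise ValidationError(
                f"lineage {self.lineage_id!r}: need 0 <= n_j <= N_j, got "
                f"n_j={self.n_present}, N_j={self.n_sampled}"
            )


@dataclass(frozen=True)
class PhyleticProfile:
    """Per-lineage presence counts for one clade; M = number of lineages."""

    clade_id: str
    lineages: tuple[LineageCount, ...]

    def __post_init__(self) -> None:
        if len({lc.lineage_id for lc in self.lineages}) != len(self.lineages):
            raise ValidationError(f"clade {self.clade_id!r}: duplicate lineage ids")

    @property
    def M(self) -> int:
        return len(self.lineages)


@dataclass(frozen=True)
class PhyleticMetric:
    clade_id: str
    S: Fraction
    D: Fraction


def phyletic_spread(profile: PhyleticProfile) -> Fraction:
    """S = m/M, the fraction of examined lineages with >= 1 representative."""
    if profile.M == 0:
        raise ValidationError(f"clade {profile.clade_id!r}: no lineages examined (M=0)")
    m = sum(1 for lc in profile.lineages if lc.n_present > 0)
    return Fraction(m, profile.M)


def phyletic_depth(profile: PhyleticProfile) -> Fraction:
    """D = Σ n_j / Σ N_j over all M lineages (the mediant of occupancies)."""
    total_sampled = sum(lc.n_sampled for lc in profile.lineages)
    if total_sampled == 0:
        raise ValidationError(f"clade {profile.clade_id!r}: Σ N_j = 0")
    total_present = sum(lc.n_present for lc in profile.lineages)
    return Fraction(total_present, total_sampled)


def phyletic_table(profiles: Iterable[PhyleticProfile]) -> pd.DataFrame:
    """One row per clade: S, D and the bar encoding (width=S, height=D)."""
    rows = []
    seen = set()
    for profile in profiles:
        if profile.clade_id in seen:
            raise ValidationError(f"duplicate clade_id {profile.clade_id!r}")
        seen.add(profile.clade_id)
        S = phyletic_spread(profile)
        D = phyletic_depth(profile)
        rows.append((profile.clade_id, float(S), float(D), float(S), float(D)))
    return pd.DataFrame(
        rows, columns=["clade_id", "S", "D", "bar_width", "bar_height"]
    )


def plot_data(table: pd.DataFrame) -> list[dict]:
    """JSON-serializable bar-graph records for downstream plotting."""
    return [
        {"clade_id": row.clade_id, "width": row.bar_width, "height": row.bar_height}
        for row in table.itertuples()
    ]


def read_profile_table(path) -> list[PhyleticProfile]:
    """Read presence TSV (clade_id, lineage_id, n_present, n_sampled)."""
    frame = pd.read_csv(path, sep="\t")
    required = ["clade_id", "lineage_id", "n_present", "n_sampled"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    profiles = []
    for clade_id, group in frame.groupby("clade_id", sort=True):
        lineages = tuple(
            LineageCount(str(r.lineage_id), int(r.n_present), int(r.n_sampled))
            for r in group.itertuples()
        )
        profiles.append(PhyleticProfile(clade_id=str(clade_id), lineages=lineages))
    return profiles


def write_profile_table(profiles: Sequence[PhyleticProfile], path) -> None:
    rows = [
        (p.clade_id, lc.lineage_id, lc.n_present, lc.n_sampled)
        for p in profiles for lc in p.lineages
    ]
    pd.DataFrame(
        rows, columns=["clade_id", "lineage_id", "n_present", "n_sampled"]
    ).to_csv(path, sep="\t", index=False)
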