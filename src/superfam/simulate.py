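"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of study input at desk scale:

* family sequence sets with controlled mean membrane propensity (a
  two-residue mixture of the scale's most hydrophobic and most hydrophilic
  residues, with the mixture weight solving the target mean in closed form);
* phyletic presence/absence counts realizing planted spread and depth;
* block-structured profile-profile comparison tables with planted
  communities;
* annotated genomes whose focal-domain neighborhoods carry a planted
  over-representation of one functional category.

All randomness flows from a single integer seed through per-stage
``numpy.random.default_rng`` substreams, so outputs are fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import DomainHit, FunctionalLabelMap, GeneRecord
from .phyletics import LineageCount, PhyleticProfile
from .simnet import ProfileComparison
from .tm import SequenceRecord, TMScale, tm_tendency_scale


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    n_sequences: int = 20
    length: int = 150
    target_mean_tm: float = 0.0
    tm_sd: float = 0.15


@dataclass(frozen=True)
class PlantedProfile:
    clade_id: str
    planted_S: float
    planted_D: float
    M: int = 20
    N_j: int | tuple[int, ...] = 10  # per-lineage species counts

    def sampled_counts(self) -> tuple[int, ...]:
        if isinstance(self.N_j, int):
            return (self.N_j,) * self.M
        if len(self.N_j) != self.M:
            raise ParameterError(
                f"clade {self.clade_id!r}: N_j has {len(self.N_j)} entries, M={self.M}"
            )
        return tuple(self.N_j)


@dataclass(frozen=True)
class CommunitySpec:
    members: tuple[str, ...]
    within_p_log10_range: tuple[float, float] = (5.0, 20.0)
    between_p_range: tuple[float, float] = (0.05, 1.0)


@dataclass(frozen=True)
class ContextSpec:
    n_genomes: int = 200
    focal_domain: str = "Lipocone"
    enriched_category: str = "lipid"
    enrichment_rate: float = 0.8
    background_rate: float = 0.2
    neighborhood_size_range: tuple[int, int] = (4, 8)
    n_neighborhoods: int = 3
    domain_pool: Mapping[str, str] = field(default_factory=lambda: dict(
        DEFAULT_DOMAIN_POOL))
    gene_length_bp: int = 900
    intergenic_gap_bp: int = 50
    between_block_gap_bp: int = 5000


#: Default domain pool: a focal membrane domain, six lipid-metabolism
#: domains (the planted enrichment class) and twenty-four background domains
#: spread evenly over three other functional categories.  With 6 enriched /
#: 24 background domains the neutral slot composition is 6/30 = 0.2, so the
#: default background_rate reproduces a composition-neutral background and
#: setting enrichment_rate equal to it yields a fully domain-exchangeable
#: null dataset.
DEFAULT_DOMAIN_POOL: dict[str, str] = {
    "Lipocone": "focal",
    "PAP2": "lipid", "CDP-OH_trans": "lipid", "Glycos_transf_1": "lipid",
    "Acyl_transf": "lipid", "PG_synthase": "lipid", "DAG_kinase": "lipid",
    "HTH_XRE": "regulation", "GGDEF": "regulation", "Sigma70_r4": "regulation",
    "SpoIIE": "regulation", "PadR": "regulation", "LytTR": "regulation",
    "MarR": "regulation", "TetR_N": "regulation",
    "ABC_tran": "transport", "MFS_1": "transport", "SecY": "transport",
    "TonB_dep": "transport", "EamA": "transport", "MATE": "transport",
    "BCCT": "transport", "OEP": "transport",
    "RHS_repeat": "conflict", "Ntox15": "conflict", "Imm52": "conflict",
    "PT-VENN": "conflict", "LXG": "conflict", "CdiA_CT": "conflict",
    "SUKH": "conflict", "Fic": "conflict",
}

#: Fraction of genomes in which an adjacency must recur to count as a
#: conserved contextual connection (see ``recommended_min_support``).
CONSERVED_ADJACENCY_FRACTION = 0.075


def recommended_min_support(n_genomes: int) -> int:
    """Support threshold separating conserved adjacency from sporadic
    juxtaposition: recurrence in >= 7.5% of genomes (at least 2)."""
    return max(2, round(CONSERVED_ADJACENCY_FRACTION * n_genomes))


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic study; the seed fixes everything."""

    seed: int = 0
    families: tuple[FamilySpec, ...] = ()
    phyletics: tuple[PlantedProfile, ...] = ()
    communities: tuple[CommunitySpec, ...] = ()
    contexts: ContextSpec | None = None


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag)])


# ---------------------------------------------------------------------------
# family sequences
# ---------------------------------------------------------------------------

def gen_family_sequences(
    spec: SimulationSpec,
    scale: TMScale | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Sequences whose per-sequence mean propensity converges to the target.

    Residues are a Bernoulli mixture of the scale's most hydrophobic and
    most hydrophilic residues; the mixture weight w solves
    ``w*h_max + (1-w)*h_min = t`` where the per-sequence target t is drawn
    N(target_mean_tm, tm_sd) truncated to the scale range.
    """
    scale = scale or tm_tendency_scale()
    h_res = scale.most_hydrophobic()
    l_res = scale.most_hydrophilic()
    h_max = scale.values[h_res]
    h_min = scale.values[l_res]
    rng = _substream(spec.seed, 1)
    records: list[SequenceRecord] = []
    assignments: list[tuple[str, str]] = []
    for fam in spec.families:
        if not h_min <= fam.target_mean_tm <= h_max:
            raise ParameterError(
                f"family {fam.family_id!r}: target mean {fam.target_mean_tm} outside "
                f"scale range [{h_min}, {h_max}]"
            )
        if fam.tm_sd < 0:
            raise ParameterError(f"family {fam.family_id!r}: tm_sd must be >= 0")
        for i in range(fam.n_sequences):
            if fam.tm_sd == 0:
                t = fam.target_mean_tm
            else:
                t = float(np.clip(
                    rng.normal(fam.target_mean_tm, fam.tm_sd), h_min, h_max))
            w = (t - h_min) / (h_max - h_min)
            draws = rng.random(fam.length) < w
            residues = "".join(h_res if hit else l_res for hit in draws)
            seq_id = f"{fam.family_id}_{i:04d}"
            records.append(SequenceRecord(
                sequence_id=seq_id, family_id=fam.family_id, residues=residues))
            assignments.append((seq_id, fam.family_id))
    table = pd.DataFrame(assignments, columns=["sequence_id", "family_id"])
    return records, table


def tm_study_families(n_families: int = 30, n_tm: int = 18,
                      n_sequences: int = 20, length: int = 150,
                      tm_target: float = 1.0, soluble_target: float = -1.0,
                      tm_sd: float = 0.15) -> tuple[FamilySpec, ...]:
    """The default superfamily layout: 30 families, 18 of them TM-propense."""
    if not 0 <= n_tm <= n_families:
        raise ParameterError("need 0 <= n_tm <= n_families")
    specs = []
    for i in range(n_families):
        is_tm = i < n_tm
        specs.append(FamilySpec(
            family_id=f"fam{i:02d}",
            n_sequences=n_sequences,
            length=length,
            target_mean_tm=tm_target if is_tm else soluble_target,
            tm_sd=tm_sd,
        ))
    return tuple(specs)


# ---------------------------------------------------------------------------
# phyletic profiles
# ---------------------------------------------------------------------------

def gen_phyletic_profiles(
    spec: SimulationSpec,
) -> tuple[list[PhyleticProfile], pd.DataFrame]:
    """Presence counts realizing the planted spread and depth.

    The number of occupied lineages is round(S*M) (so |S - planted| <=
    1/(2M)); total presence is the feasible integer nearest round(D*ΣN_j),
    distributed one-per-occupied-lineage first and then round-robin in a
    seed-shuffled lineage order.  Infeasible (S, D) combinations raise a
    ParameterError listing the feasible depth range.
    """
    rng = _substream(spec.seed, 2)
    profiles = []
    truth_rows = []
    for planted in spec.phyletics:
        if not 0.0 <= planted.planted_S <= 1.0 or not 0.0 <= planted.planted_D <= 1.0:
            raise ParameterError(
                f"clade {planted.clade_id!r}: planted S and D must lie in [0, 1]"
            )
        if planted.M < 1:
            raise ParameterError(f"clade {planted.clade_id!r}: M must be >= 1")
        N = planted.sampled_counts()
        total_sampled = sum(N)
        m = int(round(planted.planted_S * planted.M))
        # occupied lineages: a seed-chosen subset of size m
        occupied = sorted(rng.choice(planted.M, size=m, replace=False).tolist())
        cap = sum(N[j] for j in occupied)
        target_total = int(round(planted.planted_D * total_sampled))
        feasible_lo = Fraction(m, total_sampled)
        feasible_hi = Fraction(cap, total_sampled)
        if m == 0:
            if target_total != 0:
                raise ParameterError(
                    f"clade {planted.clade_id!r}: planted_S=0 forces D=0, got "
                    f"planted_D={planted.planted_D}"
                )
        elif not (feasible_lo - Fraction(1, 2 * total_sampled)
                  <= Fraction(target_total, total_sampled)
                  <= feasible_hi + Fraction(1, 2 * total_sampled)):
            raise ParameterError(
                f"clade {planted.clade_id!r}: planted_D={planted.planted_D} infeasible "
                f"for planted_S={planted.planted_S}; feasible depth range is "
                f"[{float(feasible_lo):.4f}, {float(feasible_hi):.4f}]"
            )
        target_total = max(m, min(cap, target_total))
        counts = [0] * planted.M
        for j in occupied:
            counts[j] = 1
        remaining = target_total - m
        order = list(occupied)
        rng.shuffle(order)
        for j in itertools.cycle(order) if remaining else ():
            if remaining == 0:
                break
            if counts[j] < N[j]:
                counts[j] += 1
                remaining -= 1
        lineages = tuple(
            LineageCount(lineage_id=f"lineage{j:02d}", n_present=counts[j],
                         n_sampled=N[j])
            for j in range(planted.M)
        )
        profiles.append(PhyleticProfile(clade_id=planted.clade_id, lineages=lineages))
        truth_rows.append((planted.clade_id, planted.planted_S, planted.planted_D,
                           m / planted.M, target_total / total_sampled))
    truth = pd.DataFrame(
        truth_rows,
        columns=["clade_id", "planted_S", "planted_D", "realized_S", "realized_D"],
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# profile-profile comparison tables
# ---------------------------------------------------------------------------

def gen_profile_comparisons(spec: SimulationSpec) -> list[ProfileComparison]:
    """Block-structured all-vs-all comparison records with planted communities.

    Within-community pairs draw p = 10**(-u) with u uniform in
    ``within_p_log10_range``; between-community pairs draw p uniform in
    ``between_p_range``.  Both directions of each pair are emitted with
    independent noise, mimicking non-symmetric profile-profile searches.
    """
    members_seen: set[str] = set()
    for comm in spec.communities:
        overlap = members_seen & set(comm.members)
        if overlap:
            raise ParameterError(f"families {sorted(overlap)} appear in multiple communities")
        members_seen.update(comm.members)
    rng = _substream(spec.seed, 3)
    comparisons: list[ProfileComparison] = []
    n_families = len(members_seen)

    def emit(a: str, b: str, p: float) -> None:
        comparisons.append(ProfileComparison(
            query_family=a, target_family=b, p_value=p,
            e_value=p * max(n_families, 1)))

    community_of = {
        fam: idx for idx, comm in enumerate(spec.communities) for fam in comm.members
    }
    families = sorted(members_seen)
    for a, b in itertools.combinations(families, 2):
        same = community_of[a] == community_of[b]
        if same:
            lo, hi = spec.communities[community_of[a]].within_p_log10_range
            p_ab = 10.0 ** (-rng.uniform(lo, hi))
            p_ba = 10.0 ** (-rng.uniform(lo, hi))
        else:
            # between-range convention: use the first community's range spec
            lo, hi = spec.communities[community_of[a]].between_p_range
            p_ab = float(rng.uniform(lo, hi))
            p_ba = float(rng.uniform(lo, hi))
        emit(a, b, p_ab)
        emit(b, a, p_ba)
    return comparisons


def planted_community_labels(spec: SimulationSpec) -> dict[str, int]:
    return {
        fam: idx for idx, comm in enumerate(spec.communities) for fam in comm.members
    }


def community_study_spec(seed: int = 0, n_communities: int = 4,
                         families_per_community: int = 10) -> SimulationSpec:
    """Default planted-community layout: 4 communities of 10 families."""
    communities = tuple(
        CommunitySpec(members=tuple(
            f"fam{c:02d}_{i:02d}" for i in range(families_per_community)))
        for c in range(n_communities)
    )
    return SimulationSpec(seed=seed, communities=communities)


# ---------------------------------------------------------------------------
# context datasets
# ---------------------------------------------------------------------------

def gen_context_dataset(
    spec: SimulationSpec,
) -> tuple[list[GeneRecord], list[DomainHit], FunctionalLabelMap, pd.DataFrame]:
    """Annotated genomes with one focal neighborhood per genome.

    Each genome carries ``n_neighborhoods`` tandem same-strand gene blocks
    separated by large gaps; one (seed-chosen) block contains the focal
    domain at a random slot.  Every other slot draws a domain of the
    enriched category with probability ``enrichment_rate`` inside the focal
    block and ``background_rate`` elsewhere, otherwise a uniform background
    domain.  The per-slot ground-truth draws are returned alongside.
    """
    ctx = spec.contexts
    if ctx is None:
        raise ParameterError("SimulationSpec.contexts is not set")
    lo, hi = ctx.neighborhood_size_range
    if lo < 2:
        raise ParameterError("neighborhood_size_range lower bound must be >= 2")
    if hi < lo:
        raise ParameterError("neighborhood_size_range upper bound < lower bound")
    for name, rate in (("enrichment_rate", ctx.enrichment_rate),
                       ("background_rate", ctx.background_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {rate}")
    pool = dict(ctx.domain_pool)
    if ctx.focal_domain not in pool:
        raise ParameterError(f"domain_pool lacks the focal domain {ctx.focal_domain!r}")
    categories = sorted(set(pool.values()))
    if len(categories) < 2:
        raise ParameterError("domain_pool must cover >= 2 categories")
    enriched_domains = sorted(
        d for d, cat in pool.items()
        if cat == ctx.enriched_category and d != ctx.focal_domain
    )
    background_domains = sorted(
        d for d, cat in pool.items()
        if cat != ctx.enriched_category and d != ctx.focal_domain
    )
    if not enriched_domains:
        raise ParameterError(
            f"domain_pool has no non-focal domain of category {ctx.enriched_category!r}"
        )
    if not background_domains:
        raise ParameterError("domain_pool has no background (non-enriched) domain")

    rng = _substream(spec.seed, 4)
    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    truth_rows = []
    aa_len = ctx.gene_length_bp // 3

    for g in range(ctx.n_genomes):
        genome_id = f"genome{g:04d}"
        focal_block = int(rng.integers(ctx.n_neighborhoods))
        cursor = 1
        gene_no = 0
        for block in range(ctx.n_neighborhoods):
            size = int(rng.integers(lo, hi + 1))
            is_focal_block = block == focal_block
            focal_slot = int(rng.integers(size)) if is_focal_block else -1
            rate = ctx.enrichment_rate if is_focal_block else ctx.background_rate
            for slot in range(size):
                gene_id = f"{genome_id}_g{gene_no:03d}"
                product_id = f"{genome_id}_p{gene_no:03d}"
                start = cursor
                end = cursor + ctx.gene_length_bp - 1
                cursor = end + 1 + (
                    ctx.between_block_gap_bp if slot == size - 1
                    else ctx.intergenic_gap_bp
                )
                genes.append(GeneRecord(
                    genome_id=genome_id, contig_id="contig1", gene_id=gene_id,
                    start=start, end=end, strand="+", product_id=product_id))
                if slot == focal_slot:
                    domain = ctx.focal_domain
                    from_enriched = False
                else:
                    from_enriched = bool(rng.random() < rate)
                    choices = enriched_domains if from_enriched else background_domains
                    domain = choices[int(rng.integers(len(choices)))]
                hits.append(DomainHit(
                    product_id=product_id, domain_name=domain,
                    aa_start=1, aa_end=aa_len, score=50.0, source="sim"))
                truth_rows.append((genome_id, block, is_focal_block, slot,
                                   slot == focal_slot, domain, from_enriched))
                gene_no += 1

    labels = FunctionalLabelMap(vocabulary=tuple(categories), mapping=pool)
    truth = pd.DataFrame(
        truth_rows,
        columns=["genome_id", "block", "is_focal_block", "slot", "is_focal_gene",
                 "domain", "drawn_from_enriched"],
    )
    return genes, hits, labels, truth
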