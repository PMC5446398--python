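"""T7 in-vitro-transcription templates, PCR primers and reagent stoichiometry.

Each guide is produced by T7 transcription from a single-stranded DNA oligo
of the form ``T7 promoter + N20 seed + sgRNA scaffold``. The PAM is never
part of the template: it is a genomic recognition requirement, not part of
the guide RNA. The templates are made double-stranded by PCR with a forward
primer equal to the T7 promoter and a reverse primer complementary to the
scaffold's 3' terminus.

Stoichiometry follows the treatment of a finished sequencing library:
given the library concentration and the assumed mitochondrial fraction of
its fragments, the molar amount of mtDNA target in the reaction determines
the Cas9 and gRNA amounts as fold excesses over that target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from mitocleave.genomes import reverse_complement
from mitocleave.guides import GuideSite

T7_PREFIX = "TAATACGACTCACTATAG"
SGRNA_SCAFFOLD = (
    "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCAACTTGAAAAAG"
    "TGGCACCGAGTCGGTGCTTTTTTT"
)
FORWARD_PRIMER = T7_PREFIX
REVERSE_PRIMER = "AAAAAAAGCACCGACTCGGTGC"

# build-time consistency: the reverse primer must prime the scaffold 3' end
assert SGRNA_SCAFFOLD.endswith(reverse_complement(REVERSE_PRIMER)), (
    "reverse primer is not the reverse complement of the scaffold 3' terminus"
)


@dataclass(frozen=True)
class OligoTemplate:
    """Full single-stranded T7 IVT template for one guide."""

    guide_id: str
    full_sequence: str

    @property
    def seed(self) -> str:
        return self.full_sequence[len(T7_PREFIX) : len(T7_PREFIX) + 20]

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class ReagentPlan:
    """Cas9/gRNA amounts for one library treatment reaction.

    Amounts are in pmol; concentrations in nM. ``incubation`` and ``boost``
    are protocol metadata only — they alter no computed quantity.
    """

    library_conc: float  # nM
    assumed_mito_fraction: float
    target_conc_in_library: float  # nM
    library_vol: float  # µL
    reaction_vol: float  # µL
    cas9_excess: float
    grna_excess: float
    target_amount: float  # pmol
    cas9_amount: float  # pmol
    grna_amount: float  # pmol
    target_conc_in_reaction: float  # nM
    cas9_conc_in_reaction: float  # nM
    grna_conc_in_reaction: float  # nM
    incubation_min: float = 60.0
    boost: bool = False


def build_t7_template(guide: GuideSite, guide_id: str | None = None) -> OligoTemplate:
    """T7 promoter + 20-nt seed + sgRNA scaffold; the PAM is excluded."""
    if len(guide.seed) != 20:
        raise ValueError(f"seed length {len(guide.seed)} != 20")
    if "N" in guide.seed:
        raise ValueError("seed contains N; cannot order a degenerate oligo")
    gid = guide_id or f"{guide.chrom}_{guide.cut_pos}_{guide.strand}"
    return OligoTemplate(
        guide_id=gid, full_sequence=T7_PREFIX + guide.seed + SGRNA_SCAFFOLD
    )


def emit_primers() -> tuple[str, str]:
    """The (forward, reverse) PCR primer pair used to double-strand the
    templates: forward = T7 promoter, reverse = revcomp of the scaffold
    3' terminus."""
    return FORWARD_PRIMER, REVERSE_PRIMER


def compute_target_conc(library_conc: float, mito_fraction: float) -> float:
    """Molar concentration (nM) of mtDNA target in the library.

    E.g. a 20 nM library assumed to be half mitochondrial contains a
    10 nM mtDNA target.
    """
    if not 0.0 <= mito_fraction <= 1.0:
        raise ValueError(f"mito_fraction {mito_fraction} outside [0, 1]")
    if library_conc < 0:
        raise ValueError(f"library_conc {library_conc} must be ≥ 0")
    return library_conc * mito_fraction


def reagent_plan(
    library_conc: float = 20.0,
    mito_fraction: float = 0.5,
    library_vol: float = 8.0,
    reaction_vol: float = 30.0,
    cas9_excess: float = 100.0,
    grna_excess: float = 100.0,
    incubation_min: float = 60.0,
    boost: bool = False,
) -> ReagentPlan:
    """Compute Cas9/gRNA amounts for a library digestion reaction.

    Target pmol in the reaction = library_conc (nM) × mito_fraction ×
    library_vol (µL) × 10⁻³; Cas9 and gRNA amounts are fold excesses over
    that. Defaults mirror a standard treatment: 8 µL of a 20 nM library
    (assumed 50% mitochondrial) in a 30 µL reaction with 100× Cas9 and
    100× gRNA.
    """
    if reaction_vol < library_vol:
        raise ValueError(
            f"reaction_vol {reaction_vol} µL < library_vol {library_vol} µL"
        )
    if cas9_excess < 0 or grna_excess < 0:
        raise ValueError("excess factors must be ≥ 0")
    target_conc = compute_target_conc(library_conc, mito_fraction)
    target_pmol = target_conc * library_vol * 1e-3  # nM·µL → pmol
    cas9_pmol = cas9_excess * target_pmol
    grna_pmol = grna_excess * target_pmol
    return ReagentPlan(
        library_conc=library_conc,
        assumed_mito_fraction=mito_fraction,
        target_conc_in_library=target_conc,
        library_vol=library_vol,
        reaction_vol=reaction_vol,
        cas9_excess=cas9_excess,
        grna_excess=grna_excess,
        target_amount=target_pmol,
        cas9_amount=cas9_pmol,
        grna_amount=grna_pmol,
        target_conc_in_reaction=target_pmol / reaction_vol * 1e3,
        cas9_conc_in_reaction=cas9_pmol / reaction_vol * 1e3,
        grna_conc_in_reaction=grna_pmol / reaction_vol * 1e3,
        incubation_min=incubation_min,
        boost=boost,
    )


@dataclass(frozen=True)
class CostReport:
    """Per-sample sequencing + reagent costs for untreated vs treated arms.

    All prices are caller-supplied placeholders; nothing here reflects a
    particular vendor or facility.
    """

    n_samples: int
    sequencing_cost_untreated: float
    sequencing_cost_treated: float
    reagent_cost_treated: float
    per_sample_untreated: float
    per_sample_treated: float
    breakeven_n: int | None


def cost_breakeven(
    n_samples: int,
    grna_panel_cost: float,
    cas9_cost_per_rx: float,
    lane_cost: float,
    reads_per_lane: int,
    usable_frac_untreated: float,
    usable_frac_treated: float,
    usable_reads_needed: int,
    max_n: int = 10_000,
) -> CostReport:
    """Compare per-sample cost of sequencing deeper vs treating the library.

    Sequencing cost per sample in an arm is
    ``lane_cost × (usable_reads_needed / usable_frac) / reads_per_lane``;
    the treated arm adds the panel cost amortized over ``n_samples`` plus a
    per-reaction Cas9 cost. ``breakeven_n`` is the smallest sample count at
    which the treated arm is no more expensive (found by direct scan; None
    if never within ``max_n``).
    """
    for name, frac in (
        ("usable_frac_untreated", usable_frac_untreated),
        ("usable_frac_treated", usable_frac_treated),
    ):
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"{name}={frac} outside (0, 1]")
    if n_samples < 1 or reads_per_lane < 1 or usable_reads_needed < 1:
        raise ValueError("counts must be positive")

    def seq_cost(frac: float) -> float:
        return lane_cost * (usable_reads_needed / frac) / reads_per_lane

    def per_sample_treated(n: int) -> float:
        return seq_cost(usable_frac_treated) + grna_panel_cost / n + cas9_cost_per_rx

    untreated = seq_cost(usable_frac_untreated)
    breakeven = None
    for n in range(1, max_n + 1):
        if per_sample_treated(n) <= untreated:
            breakeven = n
            break
    return CostReport(
        n_samples=n_samples,
        sequencing_cost_untreated=untreated,
        sequencing_cost_treated=seq_cost(usable_frac_treated),
        reagent_cost_treated=grna_panel_cost / n_samples + cas9_cost_per_rx,
        per_sample_untreated=untreated,
        per_sample_treated=per_sample_treated(n_samples),
        breakeven_n=breakeven,
    )


def write_order_sheet(templates: Iterable[OligoTemplate], path: str | Path) -> None:
    """TSV order sheet: guide_id, full_sequence, length."""
    with open(path, "w") as fh:
        fh.write("guide_id\tfull_sequence\tlength\n")
        for t in templates:
            fh.write(f"{t.guide_id}\t{t.full_sequence}\t{len(t)}\n")


def write_template_fasta(templates: Iterable[OligoTemplate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in templates:
            fh.write(f">{t.guide_id}\n{t.full_sequence}\n")
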