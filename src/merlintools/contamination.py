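"""Bacterial contamination screening for candidate transposase copies.

Assembly contamination is a common confounder when hunting insertion
sequences related to bacterial ISs: a hit with very high protein identity
to a bacterial sequence (> 80%, strict) is treated as a possible
contaminant outright, while moderate identity (40-80%) only becomes
suspicious when corroborated by genomic context — neighboring ORFs on the
same contig that are themselves bacterial-like.  Identity is computed over
the locally aligned region and only counts when at least half of the query
aligns, so short spurious matches cannot trigger the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from merlintools import orf_domain
from merlintools._align import local_identity

CONTAMINANT_IDENTITY = 0.80   # strict: "more than 80%"
SUSPECT_IDENTITY = 0.40
MIN_COVERAGE = 0.50


@dataclass
class ContaminationVerdict:
    best_identity: float
    coverage: float
    protein_verdict: str        # clean | suspect | contaminant
    context_verdict: str = "clean"   # clean | suspect
    rationale: str = ""

    def __post_init__(self):
        if self.protein_verdict == "contaminant" \
                and self.best_identity <= CONTAMINANT_IDENTITY:
            raise ValueError("contaminant verdict requires identity > 0.80")


def screen_protein(protein: str, bacterial_set: dict[str, str],
                   identity_threshold: float = CONTAMINANT_IDENTITY,
                   min_coverage: float = MIN_COVERAGE
                   ) -> ContaminationVerdict:
    """Best local-alignment identity of a protein against the decoy set.

    Identity strictly greater than the threshold (with sufficient query
    coverage) is called contaminant; [0.40, 0.80] is suspect pending
    context; below that, clean.
    """
    if not protein:
        raise ValueError("empty protein")
    if not bacterial_set:
        raise ValueError("bacterial reference set must be non-empty")
    best_ident = 0.0
    best_cov = 0.0
    for ref in bacterial_set.values():
        ident, cov = local_identity(protein, ref, protein=True)
        if cov >= min_coverage and ident > best_ident:
            best_ident, best_cov = ident, cov
    if best_ident > identity_threshold:
        verdict = "contaminant"
        why = (f"identity {best_ident:.2f} > {identity_threshold:.2f} "
               f"to bacterial reference")
    elif best_ident >= SUSPECT_IDENTITY:
        verdict = "suspect"
        why = (f"identity {best_ident:.2f} in [{SUSPECT_IDENTITY:.2f}, "
               f"{identity_threshold:.2f}]; needs context corroboration")
    else:
        verdict = "clean"
        why = f"identity {best_ident:.2f} below suspect range"
    return ContaminationVerdict(best_ident, best_cov, verdict,
                                rationale=why)


def screen_context(contig: str, copy_start: int, copy_end: int,
                   bacterial_set: dict[str, str], window: int = 10000,
                   min_orf_aa: int = 80) -> tuple[str, str]:
    """Are the genes around a copy bacterial-like too?

    Calls ORFs within ``window`` bp of the copy (the copy itself excluded);
    if at least two neighboring ORFs independently exceed 40% identity to
    the reference set the context is suspect.  Returns (verdict, note).
    """
    lo = max(0, copy_start - window)
    hi = min(len(contig), copy_end + window)
    neighbors = []
    for orf in orf_domain.find_orfs(contig[lo:hi], min_orf_aa):
        s, e = orf.start + lo, orf.end + lo
        if s < copy_end and e > copy_start:
            continue  # overlaps the copy itself
        neighbors.append(orf)
    if not neighbors:
        return "clean", "no neighboring ORFs callable in window"
    n_bacterial = 0
    for orf in neighbors:
        v = screen_protein(orf.protein, bacterial_set)
        if v.best_identity > SUSPECT_IDENTITY:
            n_bacterial += 1
            if n_bacterial >= 2:
                return "suspect", (f"{n_bacterial}+ neighboring ORFs "
                                   f"> {SUSPECT_IDENTITY:.0%} bacterial identity")
    return "clean", f"{n_bacterial} of {len(neighbors)} neighbors bacterial-like"


def screen_copy(protein: str, contig: str, copy_start: int, copy_end: int,
                bacterial_set: dict[str, str], window: int = 10000
                ) -> ContaminationVerdict:
    """Protein screen plus context corroboration for one copy."""
    verdict = screen_protein(protein, bacterial_set)
    ctx, note = screen_context(contig, copy_start, copy_end, bacterial_set,
                               window)
    verdict.context_verdict = ctx
    verdict.rationale += f"; context: {note}"
    if verdict.protein_verdict == "suspect" and ctx != "suspect":
        # moderate identity without bacterial neighborhood: stand down
        verdict.rationale += " (no context corroboration)"
    return verdict
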