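"""Reconstruction scenarios mirroring published Merlin family structures.

Each scenario plants elements whose structural parameters follow a family
described in the literature, so the detectors can be checked against the
published numbers:

* ``porphyridium_like`` — the red-alga (*Porphyridium purpureum*) family:
  two near-identical copies (99% nt identity), imperfect 39-bp TIRs,
  9-bp TSDs.
* ``symbiodinium_f1_like`` — *Symbiodinium microadriaticum* Sy.m_F1:
  51-bp TIRs, 8-bp TSDs, ~2.57-kb span, and a 5' tandem array of 2.3 units
  of a 52-bp repeat containing 5 units of a 6-bp repeat.
* ``symbiodinium_kawagutii_f1_like`` — Sy.k_F1: highly imperfect TIRs with
  12 mismatches in the first 26 positions.
* ``symbiodinium_kawagutii_f2_like`` — Sy.k_F2 copy 1: 26-bp TIRs and a
  163-bp tandem repeat in 4 units.
* ``monocercomonoides_like`` — seven distinct families in one genome, all
  with 8-bp TSDs and TIRs of 23-29 bp.
* ``perkinsela_like`` — kinetoplastid reference copy: 762 bp, TIR/TSD-less
  context not modelled here (the length is the structural datum).
"""

from __future__ import annotations

from merlintools.simgenome import FamilySpec, TandemSpec


def porphyridium_like() -> FamilySpec:
    return FamilySpec("Pp_F1", tir_length=39, tir_mismatches=3,
                      tsd_length=9, orf_length=319, n_copies=2,
                      per_copy_divergence=0.005)


def symbiodinium_f1_like() -> FamilySpec:
    return FamilySpec(
        "Sym_F1", tir_length=51, tir_mismatches=4, tsd_length=8,
        orf_length=600, n_copies=3, per_copy_divergence=0.005,
        element_length=2570,
        tandem_spec=TandemSpec(period=52, units=2.3, inner_period=6,
                               inner_units=5))


def symbiodinium_kawagutii_f1_like() -> FamilySpec:
    return FamilySpec("Syk_F1", tir_length=26, tir_mismatches=12,
                      tsd_length=8, orf_length=400, n_copies=3,
                      per_copy_divergence=0.005)


def symbiodinium_kawagutii_f2_like() -> FamilySpec:
    return FamilySpec("Syk_F2", tir_length=26, tir_mismatches=2,
                      tsd_length=8, orf_length=300, n_copies=2,
                      per_copy_divergence=0.01,
                      element_length=1800,
                      tandem_spec=TandemSpec(period=163, units=4.0))


def monocercomonoides_like() -> list[FamilySpec]:
    specs = []
    for i, tir_len in enumerate((23, 24, 25, 26, 27, 28, 29), start=1):
        specs.append(FamilySpec(f"Msp_F{i}", tir_length=tir_len,
                                tir_mismatches=1 + i % 3, tsd_length=8,
                                orf_length=200, n_copies=2,
                                per_copy_divergence=0.01))
    return specs


def perkinsela_like() -> FamilySpec:
    # 762-bp reference copy; 252-codon ORF fills most of the element
    return FamilySpec("Psp_ref", tir_length=20, tsd_length=8,
                      orf_length=160, n_copies=2,
                      per_copy_divergence=0.0, element_length=762)
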