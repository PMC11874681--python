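"""SWS1 spectral-tuning classification at bovine-rhodopsin sites 114/118.

Visual-pigment tuning sites are conventionally numbered by aligning the
query opsin to bovine rhodopsin (BRH) and reporting residues by the BRH
position they occupy. For UV-sensitive SWS1 pigments, sites 114 and 118
evolve in tandem and shift peak sensitivity by ~10 nm: the A114/A118
genotype marks the shorter-wavelength phenotype (lambda_max ~360 nm) and
S114/S118 the longer-wavelength phenotype (~370 nm). Any other combination
is left unassigned — only the two tandem genotypes have an established
spectral prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = ["BRH_REFERENCE", "BrhSiteCall", "translate_cds", "map_to_brh", "classify_sws1", "call_sws1"]

#: Bovine rhodopsin (348 aa), the standard numbering reference for opsin
#: tuning sites (canonical landmarks: E113 counterion, K296 retinal
#: attachment, NPVIY 302-306).
BRH_REFERENCE = (
    "MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLYVTVQHKKLRTPLNYILLNLAVADLFMVFGG"
    "FTTTLYTSLHGYFVFGPTGCNLEGFFATLGGEIALWSLVVLAIERYVVVCKPMSNFRFGENHAIMGVAFTWVMALACAAPPLVGWSRYIPEGMQCSCGID"
    "YYTPHEETNNESFVIYMFVVHFIIPLIVIFFCYGQLVFTVKEAAAQQQESATTQKAEKEVTRMVIIMVIAFLICWLPYAGVAFYIFTHQGSDFGPIFMTI"
    "PAFFAKTSAVYNPVIYIMMNKQFRNCMVTTLCCGKNPLGDDEASTTVSKTETSQVAPA"
)

LAMBDA_SHORT_NM = 360
LAMBDA_LONG_NM = 370

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class BrhSiteCall:
    """Residues at BRH 114/118 with the resulting UV phenotype call."""

    gene_label: str
    residue_114: str
    residue_118: str
    phenotype: str  # 'short' | 'long' | 'unassigned'
    lambda_max_nm: int | None


def translate_cds(cds: str) -> str:
    """Translate a frame-0 CDS (standard code), dropping a terminal stop."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def map_to_brh(
    protein: str,
    brh_reference: str = BRH_REFERENCE,
    min_identity: float = 0.15,
    length_bounds: tuple[int, int] = (200, 500),
) -> dict[int, str]:
    """Map each 1-based BRH site to the aligned query residue (or '-').

    The query is globally aligned to the reference (BLOSUM62, affine gaps).
    Queries outside ``length_bounds`` or below the identity floor are
    rejected as non-opsins.
    """
    if not protein:
        raise ValueError("empty query protein")
    lo, hi = length_bounds
    if not (lo <= len(protein) <= hi):
        raise ValueError(f"query length {len(protein)} outside [{lo}, {hi}]")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(brh_reference, protein)[0]
    idx = aln.indices
    mapping: dict[int, str] = {}
    matches = comparable = 0
    for col in range(idx.shape[1]):
        ir, iq = int(idx[0, col]), int(idx[1, col])
        if ir < 0:
            continue
        res = protein[iq] if iq >= 0 else "-"
        mapping[ir + 1] = res  # BRH numbering is 1-based
        if iq >= 0:
            comparable += 1
            if brh_reference[ir] == res:
                matches += 1
    if comparable == 0 or matches / len(brh_reference) < min_identity:
        raise ValueError("alignment identity below floor; query does not look like an opsin")
    return mapping


def classify_sws1(residue_114: str, residue_118: str, gene_label: str = "") -> BrhSiteCall:
    """UV phenotype from the tandem 114/118 genotype.

    (A, A) -> short, 360 nm; (S, S) -> long, 370 nm; anything else is
    unassigned with no lambda_max prediction.
    """
    for r in (residue_114, residue_118):
        if r != "-" and r.upper() not in _AA:
            raise ValueError(f"not an amino-acid symbol: {r!r}")
    r114, r118 = residue_114.upper(), residue_118.upper()
    if (r114, r118) == ("A", "A"):
        return BrhSiteCall(gene_label, r114, r118, "short", LAMBDA_SHORT_NM)
    if (r114, r118) == ("S", "S"):
        return BrhSiteCall(gene_label, r114, r118, "long", LAMBDA_LONG_NM)
    warnings.warn(
        f"{gene_label or 'query'}: genotype ({r114},{r118}) matches neither tandem "
        "phenotype; left unassigned"
    )
    return BrhSiteCall(gene_label, r114, r118, "unassigned", None)


def call_sws1(sequence: str, gene_label: str = "", is_protein: bool | None = None) -> BrhSiteCall:
    """Full call for one SWS1 sequence (nucleotide CDS or protein)."""
    if is_protein is None:
        is_protein = any(c.upper() not in "ACGTN" for c in sequence)
    protein = sequence if is_protein else translate_cds(sequence)
    sites = map_to_brh(protein)
    return classify_sws1(sites.get(114, "-"), sites.get(118, "-"), gene_label)


def write_calls_tsv(calls: Iterable[BrhSiteCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tres114\tres118\tphenotype\tlambda_max_nm\n")
        for c in calls:
            lam = "" if c.lambda_max_nm is None else c.lambda_max_nm
            fh.write(f"{c.gene_label}\t{c.residue_114}\t{c.residue_118}\t{c.phenotype}\t{lam}\n")
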