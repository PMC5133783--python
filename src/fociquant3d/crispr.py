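"""Sequence-level verification arithmetic for CRISPR-Cas9 editing experiments.

Covers protospacer localization against a template (20-nt guide followed by a
5'-NGG PAM, optionally the 5'-NAG alternative), the canonical SpCas9 blunt
cut 3 bp 5' of the PAM, Surveyor cleavage-fragment prediction, indel-fraction
estimation from band intensities, and exact-match in-silico PCR.

The indel estimate follows the standard Surveyor densitometry formula:
``f_cut = (b + c) / (a + b + c)`` for the uncut band ``a`` and cleavage bands
``b``, ``c``; ``indel% = 100 (1 - sqrt(1 - f_cut))``, which accounts for
cleaved heteroduplexes forming between one edited and one unedited strand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from Bio.Seq import Seq

#: Offset of the blunt cut from the protospacer start (between nt 17 and 18,
#: i.e. 3 nt 5' of the PAM).
CUT_OFFSET = 17

#: sgRNAs targeting NSMCE2 exon 3 (overlapping protospacers) and the primer
#: pair flanking the 417-bp Surveyor amplicon.
NSMCE2_SG1 = "TTCCAAGCCTGTATCAACTC"
NSMCE2_SG2 = "AGCCTGTATCAACTCTGGTA"
SURVEYOR_FWD_PRIMER = "AATTTCAAGATGCCAGGACGT"
SURVEYOR_REV_PRIMER = "GGATCTTCAAATCTTTGCCCAT"


class PCRError(ValueError):
    """Raised when in-silico PCR yields no product or multiple products."""


def _clean(seq: str, name: str = "sequence") -> str:
    s = re.sub(r"\s", "", str(seq)).upper()
    if not s or re.search(r"[^ACGT]", s):
        raise ValueError(f"{name} must be non-empty A/C/G/T only")
    return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GuideTarget:
    """A protospacer hit on a template, in forward-frame coordinates.

    ``start`` is the 0-based offset of the 20-nt match on the forward strand;
    ``cut_site`` is the position of the blunt cut such that the 5' fragment of
    a product starting at 0 has length ``cut_site``.
    """

    guide: str
    pam: str
    strand: str
    start: int
    cut_site: int


def _occurrences(haystack: str, needle: str):
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_protospacer(
    template: str, guide: str, allow_nag: bool = False
) -> list[GuideTarget]:
    """Exact protospacer matches on both strands with a valid PAM.

    Reverse-strand hits are reported in forward-frame coordinates (the match
    covers ``[start, start + 20)`` and the PAM lies immediately 5' of it on
    the forward strand).  An absent target yields an empty list.
    """
    t = _clean(template, "template")
    g = _clean(guide, "guide")
    if len(g) != 20:
        raise ValueError("guide must be exactly 20 nt")
    pams = ("GG", "AG") if allow_nag else ("GG",)
    hits: list[GuideTarget] = []
    for i in _occurrences(t, g):
        pam = t[i + 20 : i + 23]
        if len(pam) == 3 and pam[1:] in pams:
            hits.append(GuideTarget(g, pam, "+", i, i + CUT_OFFSET))
    grc = reverse_complement(g)
    for i in _occurrences(t, grc):
        pam_fwd = t[i - 3 : i]
        if len(pam_fwd) == 3:
            pam = reverse_complement(pam_fwd)
            if pam[1:] in pams:
                hits.append(GuideTarget(g, pam, "-", i, i + 3))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def predict_fragments(amplicon_length: int, cut_site: int) -> tuple[int, int]:
    """Surveyor cleavage fragment lengths (5', 3') for a cut inside an amplicon."""
    if not 0 < cut_site < amplicon_length:
        raise ValueError("cut_site must lie strictly inside the amplicon")
    return (cut_site, amplicon_length - cut_site)


@dataclass
class SurveyorResult:
    a: float
    b: float
    c: float
    cut_fraction: float
    indel_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut_fraction <= 1.0:
            raise ValueError("cut_fraction out of [0,1]")
        if not 0.0 <= self.indel_percent <= 100.0:
            raise ValueError("indel_percent out of [0,100]")


def indel_fraction(a: float, b: float, c: float) -> SurveyorResult:
    """Indel occurrence from Surveyor band intensities (uncut a; cleaved b, c)."""
    if min(a, b, c) < 0:
        raise ValueError("band intensities must be non-negative")
    total = a + b + c
    if total <= 0:
        raise ValueError("total band intensity must be positive")
    f_cut = min((b + c) / total, 1.0)
    indel = 100.0 * (1.0 - math.sqrt(1.0 - f_cut))
    return SurveyorResult(a=a, b=b, c=c, cut_fraction=f_cut,
                          indel_percent=float(min(max(indel, 0.0), 100.0)))


def cut_fraction_from_indel(indel_percent: float) -> float:
    """Inverse of the indel formula (round-trip identity with indel_fraction)."""
    if not 0.0 <= indel_percent <= 100.0:
        raise ValueError("indel_percent out of [0,100]")
    return 1.0 - (1.0 - indel_percent / 100.0) ** 2


@dataclass
class PCRProduct:
    sequence: str
    start: int  # forward-frame start of the amplicon in the template
    end: int  # exclusive

    @property
    def length(self) -> int:
        return len(self.sequence)


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> PCRProduct:
    """Exact-match PCR amplicon prediction.

    The amplicon spans from the forward primer's 5' end to the 5' end of the
    reverse primer's binding site on the forward strand, inclusive.  The
    reverse primer may be given either in its synthesis orientation (its
    reverse complement is searched on the forward strand) or already
    reverse-complemented.  Exactly one product is required.
    """
    t = _clean(template, "template")
    f = _clean(fwd_primer, "forward primer")
    r = _clean(rev_primer, "reverse primer")
    if len(f) < 15 or len(r) < 15:
        raise ValueError("primers must be >= 15 nt")
    rev_site = reverse_complement(r)
    rev_hits = list(_occurrences(t, rev_site))
    if not rev_hits:
        # primer possibly supplied already reverse-complemented
        rev_hits = list(_occurrences(t, r))
        rev_site = r
    products = []
    for i in _occurrences(t, f):
        for j in rev_hits:
            end = j + len(rev_site)
            if end > i + len(f) and j >= i:
                products.append((i, end))
    if not products:
        raise PCRError("no product: primer pair does not amplify this template")
    if len(products) > 1:
        raise PCRError(f"{len(products)} products predicted: {products}")
    i, end = products[0]
    return PCRProduct(sequence=t[i:end], start=i, end=end)


def surveyor_report(
    template: str,
    guides: list[str] | str,
    fwd_primer: str,
    rev_primer: str,
    allow_nag: bool = False,
    band_intensities: dict | None = None,
) -> dict:
    """End-to-end Surveyor prediction: amplicon, cut sites, fragment sizes and,
    when band intensities are supplied per guide, the estimated indel percent.
    """
    if isinstance(guides, str):
        guides = [guides]
    product = in_silico_pcr(template, fwd_primer, rev_primer)
    report: dict = {
        "amplicon_length_bp": product.length,
        "amplicon_start": product.start,
        "guides": [],
    }
    for g in guides:
        hits = find_protospacer(product.sequence, g, allow_nag=allow_nag)
        entry: dict = {"guide": g, "n_sites": len(hits), "sites": []}
        for h in hits:
            frag5, frag3 = predict_fragments(product.length, h.cut_site)
            entry["sites"].append(
                {
                    "strand": h.strand,
                    "pam": h.pam,
                    "cut_site": h.cut_site,
                    "fragments_bp": [frag5, frag3],
                }
            )
        if band_intensities and g in band_intensities:
            a, b, c = band_intensities[g]
            res = indel_fraction(a, b, c)
            entry["cut_fraction"] = res.cut_fraction
            entry["indel_percent"] = res.indel_percent
        report["guides"].append(entry)
    return report
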