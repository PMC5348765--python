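"""Structural annotation of classified loci.

ORF finding, LTR-pair detection by aligning the element's flanks against
each other, zinc-knuckle (CCHC) motif scanning, domain-architecture
ordering, and the active-site audit of RNase H domains against the
canonical D-E-D-R/H-D residue pattern (arginine in aRNH, histidine in
fmRNH, unconstrained at the semiconservative site in the Ty3/Gypsy gRNH).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .profiles import (
    DomainHit,
    DomainProfile,
    translate_six_frames,
    viterbi_search,
)

#: display labels used in architecture strings
DISPLAY_LABELS = {
    "aRNH": "aRH",
    "fmRNH": "fmRH",
    "gRNH": "gRH",
    "INT": "IN",
    "RT_LTR": "RT",
    "RT_nonLTR": "RT",
    "PR": "PR",
    "CHD": "CHD",
    "EN": "EN",
    "RLE": "RLE",
    "CCHC": "CCHC",
}

#: canonical catalytic residues per RNase H subtype; '.' = unconstrained
CANONICAL_AUDIT = {
    "aRNH": "DEDRD",
    "fmRNH": "DEDHD",
    "gRNH": "DED.D",
}


@dataclass
class Orf:
    """An open reading frame within a window (nt coords, 0-based half-open;
    the interval includes the stop codon when one terminates the ORF)."""

    start: int
    end: int
    strand: str
    frame: int
    protein: str
    has_stop: bool


def find_orfs(window_sequence: str, min_protein_length: int = 100) -> list[Orf]:
    """All maximal ATG-to-stop reading frames on both strands with protein
    length >= threshold. ORFs running off the window end (no stop) are
    reported too, since mining windows truncate elements."""
    orfs: list[Orf] = []
    for frame, protein, mapper in translate_six_frames(window_sequence):
        segment_start = 0
        i = 0
        n = len(protein)
        while segment_start < n:
            stop = protein.find("*", segment_start)
            seg_end = stop if stop != -1 else n
            atg = protein.find("M", segment_start, seg_end)
            if atg != -1 and seg_end - atg >= min_protein_length:
                prot = protein[atg:seg_end]
                last = seg_end if stop == -1 else seg_end + 1  # include stop codon
                a = mapper.interval(atg, last)
                orfs.append(
                    Orf(a[0], a[1], "+" if frame > 0 else "-", frame, prot,
                        has_stop=stop != -1)
                )
            segment_start = seg_end + 1
            i += 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


@dataclass
class LtrPair:
    five_prime: tuple[int, int]  # window coords, 0-based half-open
    three_prime: tuple[int, int]
    identity: float


def make_nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def detect_ltr(
    element_window: str,
    candidate_span: tuple[int, int],
    min_len: int = 100,
    min_identity: float = 0.8,
    max_flank: int = 5_000,
) -> Optional[LtrPair]:
    """LTR pair by local self-alignment of the flanks of the ORF region.

    The upstream flank (up to ``max_flank`` nt before the span) is aligned
    locally against the downstream flank; the best alignment is reported as
    the pair when its aligned length reaches ``min_len`` and identity
    reaches ``min_identity``.
    """
    span_start, span_end = candidate_span
    if not (0 <= span_start <= span_end <= len(element_window)):
        raise ValueError("candidate span outside window")
    up_off = max(0, span_start - max_flank)
    upstream = element_window[up_off:span_start]
    downstream = element_window[span_end : span_end + max_flank]
    if not upstream or not downstream:
        return None
    aligner = make_nucleotide_aligner()
    alignments = aligner.align(upstream, downstream)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    best = alignments[0]
    blocks_up, blocks_down = best.aligned
    if len(blocks_up) == 0:
        return None
    matches = comparable = 0
    a, b = best[0], best[1]
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            matches += 1
    up_span = (int(blocks_up[0][0]), int(blocks_up[-1][1]))
    down_span = (int(blocks_down[0][0]), int(blocks_down[-1][1]))
    length = min(up_span[1] - up_span[0], down_span[1] - down_span[0])
    identity = matches / comparable if comparable else 0.0
    if length < min_len or identity < min_identity:
        return None
    return LtrPair(
        five_prime=(up_off + up_span[0], up_off + up_span[1]),
        three_prime=(span_end + down_span[0], span_end + down_span[1]),
        identity=identity,
    )


def find_cchc(protein: str, spacing: tuple[int, int, int] = (2, 4, 4)) -> list[int]:
    """0-based start positions of the zinc-knuckle pattern
    C-x(2)-C-x(4)-H-x(4)-C (spacings configurable); overlapping matches
    are all reported."""
    s1, s2, s3 = spacing
    pattern = re.compile(rf"(?=(C.{{{s1}}}C.{{{s2}}}H.{{{s3}}}C))")
    return [m.start() for m in pattern.finditer(protein)]


def cchc_span_length(spacing: tuple[int, int, int] = (2, 4, 4)) -> int:
    return 4 + sum(spacing)


def audit_catalytic_residues(
    rnh_hit: DomainHit, profile: DomainProfile
) -> tuple[str, str, str, str, str]:
    """Residues of the target aligned to the profile's five catalytic match
    states ('-' when the state is deleted or outside the hit). Read from
    the Viterbi state path."""
    if profile.catalytic_states is None:
        raise ValueError(f"profile {profile.name} declares no catalytic states")
    if not rnh_hit.aligned_state_path:
        raise ValueError("hit lacks an aligned state path")
    residue_at_state: dict[int, str] = {}
    for op, state, pos in rnh_hit.aligned_state_path:
        if op == "M":
            residue_at_state[state] = rnh_hit.matched_protein[
                pos - rnh_hit.protein_start
            ]
        elif op == "D":
            residue_at_state[state] = "-"
    audit = tuple(residue_at_state.get(s, "-") for s in profile.catalytic_states)
    assert len(audit) == 5
    return audit  # type: ignore[return-value]


def is_degenerate(audit: Sequence[str], family: str) -> bool:
    """True when the audited residues depart from the canonical
    D-E-D-R/H-D pattern of the family."""
    canonical = CANONICAL_AUDIT[family]
    return any(
        exp != "." and obs != exp for obs, exp in zip(audit, canonical)
    )


def architecture_string(
    domain_hits: Iterable[tuple[str, int, int]],
    cchc_positions: Iterable[int] = (),
    cchc_spacing: tuple[int, int, int] = (2, 4, 4),
) -> list[str]:
    """Ordered display labels of the domains along a protein.

    ``domain_hits`` are (profile_name, protein_start, protein_end) tuples;
    CCHC motif positions are merged in at their protein coordinate. The
    result is invariant to input order (sorted by start coordinate).
    """
    entries = [
        (start, end, DISPLAY_LABELS.get(name, name))
        for name, start, end in domain_hits
    ]
    span = cchc_span_length(cchc_spacing)
    covered = [(s, e) for s, e, _ in entries]
    for pos in cchc_positions:
        # a knuckle inside an already-annotated domain is not a separate unit
        if any(s <= pos < e for s, e in covered):
            continue
        entries.append((pos, pos + span, "CCHC"))
    entries.sort(key=lambda t: (t[0], t[1]))
    return [label for _, _, label in entries]


def has_dual_rnh(architecture: Sequence[str]) -> bool:
    """gRH immediately followed by aRH (the 'dual RNase H' arrangement)."""
    return any(
        a == "gRH" and b == "aRH"
        for a, b in zip(architecture, architecture[1:])
    )


def has_int_chd_fusion(
    domain_hits: Iterable[tuple[str, int, int]], max_gap: int = 300
) -> bool:
    """CHD starting within ``max_gap`` residues after the integrase end."""
    hits = list(domain_hits)
    int_ends = [e for n, s, e in hits if DISPLAY_LABELS.get(n, n) == "IN"]
    chd_starts = [s for n, s, e in hits if DISPLAY_LABELS.get(n, n) == "CHD"]
    return any(
        0 <= cs - ie <= max_gap for ie in int_ends for cs in chd_starts
    )


@dataclass
class ElementAnnotation:
    """Full structural model of one locus."""

    genome_id: str
    window: tuple[int, int]
    classification: str
    group: str
    orfs: list[Orf] = field(default_factory=list)
    domain_hits: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (orf key, profile name, protein start, protein end)
    architecture: list[str] = field(default_factory=list)
    ltr_pair: Optional[LtrPair] = None
    cchc_sites: list[int] = field(default_factory=list)
    catalytic_audit: dict[str, tuple[str, ...]] = field(default_factory=dict)
    degenerate: dict[str, bool] = field(default_factory=dict)

    def architecture_label(self) -> str:
        return "-".join(self.architecture)


def annotate_window(
    genome_id: str,
    window: tuple[int, int],
    window_sequence: str,
    classification: str,
    group: str,
    profiles: Mapping[str, DomainProfile],
    min_protein_length: int = 100,
    ltr_min_len: int = 100,
    ltr_min_identity: float = 0.8,
    cchc_spacing: tuple[int, int, int] = (2, 4, 4),
) -> ElementAnnotation:
    """Annotate one classified window: ORFs, per-ORF domain hits, the
    architecture of the domain-richest (pol) ORF, CCHC sites, LTR pair for
    LTR-classified loci, and the catalytic audit of every RNase H hit."""
    ann = ElementAnnotation(genome_id, window, classification, group)
    ann.orfs = find_orfs(window_sequence, min_protein_length=min_protein_length)
    per_orf_hits: dict[int, list[tuple[str, int, int]]] = {}
    audits: dict[str, tuple[str, ...]] = {}
    degenerate: dict[str, bool] = {}
    for idx, orf in enumerate(ann.orfs):
        for name, profile in profiles.items():
            for hit in viterbi_search(profile, orf.protein, target_id=f"orf{idx}"):
                per_orf_hits.setdefault(idx, []).append(
                    (name, hit.protein_start, hit.protein_end)
                )
                ann.domain_hits.append(
                    (f"orf{idx}", name, hit.protein_start, hit.protein_end)
                )
                if profile.catalytic_states is not None:
                    audit = audit_catalytic_residues(hit, profile)
                    key = f"orf{idx}:{name}"
                    audits[key] = audit
                    degenerate[key] = is_degenerate(audit, name)
    ann.catalytic_audit = audits
    ann.degenerate = degenerate
    if per_orf_hits:
        pol_idx = max(per_orf_hits, key=lambda i: (len(per_orf_hits[i]), -i))
        pol_orf = ann.orfs[pol_idx]
        ann.cchc_sites = find_cchc(pol_orf.protein, spacing=cchc_spacing)
        ann.architecture = architecture_string(
            per_orf_hits[pol_idx], ann.cchc_sites, cchc_spacing
        )
    if classification == "LTR_RT" and ann.orfs:
        span = (min(o.start for o in ann.orfs), max(o.end for o in ann.orfs))
        ann.ltr_pair = detect_ltr(
            window_sequence, span, min_len=ltr_min_len, min_identity=ltr_min_identity
        )
    return ann
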