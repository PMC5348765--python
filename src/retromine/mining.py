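"""Anchor-and-classify mining of aRNH-carrying loci.

The mining algorithm follows four steps: (1) map aRNH domains on six-frame
translations of the genome, (2) expand a window of up to 10 kb on each side
of every anchor (clamped at contig edges), (3) screen each window for
reverse-transcriptase domains with the LTR-RT and non-LTR-RT profiles, and
(4) split loci into LTR retrotransposons, non-LTR retrotransposons, and
RT-free "individual" RNase H loci, assigning group identity (Chronos,
Archon, L1, Utopia) by local protein alignment against seed references.
Fungi/Metazoa-type RNase H genes are mined the same way with 1 kb flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .profiles import (
    DomainHit,
    DomainProfile,
    _reciprocal_overlap,
    scan_genome,
    translate_six_frames,
)

logger = logging.getLogger(__name__)

LTR_RT = "LTR_RT"
NONLTR_RT = "NONLTR_RT"
INDIVIDUAL_RNH = "INDIVIDUAL_RNH"

RT_GROUPS = ("Chronos", "Archon", "L1", "Utopia")


@dataclass
class CandidateLocus:
    """An aRNH/fmRNH-anchored genomic window with its classification."""

    genome_id: str
    anchor: DomainHit
    window: tuple[int, int]
    rt_hits: list[DomainHit] = field(default_factory=list)
    classification: Optional[str] = None
    group: str = "unassigned"
    chd_hits: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        gs, ge = self.anchor.genome_interval()
        ws, we = self.window
        if not (ws <= gs and ge <= we):
            raise ValueError("window must contain the anchor interval")


def expand_window(anchor: DomainHit, genome_length: int,
                  half_width: int = 10_000) -> tuple[int, int]:
    """Window of up to ``half_width`` nt on each side of the anchor,
    clamped at contig edges ("when possible")."""
    gs, ge = anchor.genome_interval()
    return max(0, gs - half_width), min(genome_length, ge + half_width)


def merge_anchor_windows(loci: Sequence[CandidateLocus]) -> list[CandidateLocus]:
    """Collapse loci whose anchors overlap reciprocally >50% on genome
    coordinates (e.g. one domain reported in two frames), keeping the
    best-scoring anchor. Non-overlapping windows are untouched."""
    ranked = sorted(
        loci, key=lambda l: (-l.anchor.score, l.anchor.genome_start, l.anchor.frame)
    )
    kept: list[CandidateLocus] = []
    for locus in ranked:
        iv = locus.anchor.genome_interval()
        if all(
            _reciprocal_overlap(iv, k.anchor.genome_interval()) <= 0.5 for k in kept
        ):
            kept.append(locus)
    kept.sort(key=lambda l: (l.anchor.genome_start, l.anchor.genome_end))
    return kept


def _offset_hits(hits: Iterable[DomainHit], offset: int) -> list[DomainHit]:
    for h in hits:
        h.genome_start += offset
        h.genome_end += offset
    return list(hits)


def classify_locus(
    window_sequence: str,
    rt_ltr_profile: DomainProfile,
    rt_nonltr_profile: DomainProfile,
    target_id: str = "window",
) -> tuple[str, list[DomainHit]]:
    """Classify one window by co-localized RT evidence.

    No RT hit from either profile -> INDIVIDUAL_RNH; hits from one profile
    -> that class; hits from both -> the class of the higher-scoring hit
    (tie -> LTR_RT, logged). Returns (classification, RT hits in window
    coordinates).
    """
    ltr_hits = scan_genome(target_id, window_sequence, rt_ltr_profile)
    nonltr_hits = scan_genome(target_id, window_sequence, rt_nonltr_profile)
    if not ltr_hits and not nonltr_hits:
        return INDIVIDUAL_RNH, []
    if ltr_hits and not nonltr_hits:
        return LTR_RT, ltr_hits
    if nonltr_hits and not ltr_hits:
        return NONLTR_RT, nonltr_hits
    best_ltr = max(h.score for h in ltr_hits)
    best_nonltr = max(h.score for h in nonltr_hits)
    if best_ltr == best_nonltr:
        logger.info("RT-ambiguous window %s: tie at %.2f bits, resolved as LTR_RT",
                    target_id, best_ltr)
        return LTR_RT, sorted(ltr_hits + nonltr_hits, key=lambda h: h.genome_start)
    winner = LTR_RT if best_ltr > best_nonltr else NONLTR_RT
    return winner, sorted(ltr_hits + nonltr_hits, key=lambda h: h.genome_start)


def make_protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def alignment_identity(alignment) -> float:
    """Fraction of identical residues over aligned (non-gap) columns."""
    a, b = alignment[0], alignment[1]
    matches = comparable = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            matches += 1
    return matches / comparable if comparable else 0.0


def assign_group(
    locus_proteins: str | Sequence[str],
    references: Mapping[str, str],
    min_identity: float = 0.35,
    min_ratio: float = 1.2,
    chd_present: Optional[bool] = None,
) -> str:
    """Best-reference group assignment by local protein alignment.

    ``locus_proteins`` is the locus coding sequence (one protein, or the six
    frame translations of the window — frameshifted copies then still carry
    a long alignable segment in one of the frames). The best-scoring group
    wins if the best alignment's identity >= ``min_identity`` and the
    best/second-best score ratio >= ``min_ratio``; otherwise "unassigned".
    Chronos and Archon share most of their pol, so when the winner is one of
    them the ratio is measured against the best group outside the pair, and
    chromodomain presence (when supplied) decides between the two
    (CHD present -> Chronos).
    """
    if isinstance(locus_proteins, str):
        locus_proteins = [locus_proteins]
    if not references:
        raise ValueError("references must be non-empty")
    aligner = make_protein_aligner("local")
    scores: dict[str, float] = {}
    best_pair: dict[str, tuple[float, str]] = {}
    for group, ref in references.items():
        best = 0.0
        best_prot = ""
        for prot in locus_proteins:
            clean = prot.replace("*", "X")
            if not clean:
                continue
            s = aligner.score(clean, ref)
            if s > best:
                best, best_prot = s, clean
        scores[group] = best
        best_pair[group] = (best, best_prot)
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    winner = ordered[0]
    if scores[winner] <= 0:
        return "unassigned"
    if winner in ("Chronos", "Archon"):
        rivals = [scores[g] for g in ordered if g not in ("Chronos", "Archon")]
    else:
        rivals = [scores[g] for g in ordered[1:]]
    runner_up = max(rivals) if rivals else 0.0
    if runner_up > 0 and scores[winner] / runner_up < min_ratio:
        return "unassigned"
    _, prot = best_pair[winner]
    alignment = aligner.align(prot, references[winner])[0]
    if alignment_identity(alignment) < min_identity:
        return "unassigned"
    if winner in ("Chronos", "Archon") and chd_present is not None:
        winner = "Chronos" if chd_present else "Archon"
    return winner


def mine_genome(
    genome_id: str,
    sequence: str,
    arnh_profile: DomainProfile,
    rt_ltr_profile: DomainProfile,
    rt_nonltr_profile: DomainProfile,
    references: Mapping[str, str],
    chd_profile: DomainProfile | None = None,
    half_width: int = 10_000,
    min_identity: float = 0.35,
    min_ratio: float = 1.2,
) -> list[CandidateLocus]:
    """Run the full anchor -> window -> RT screen -> group pipeline on one
    genome sequence. Individual-aRNH loci come back with group "aRNH"
    (clade labels are assigned later by the phylogenetic clustering)."""
    length = len(sequence)
    anchors = scan_genome(genome_id, sequence, arnh_profile)
    loci = [
        CandidateLocus(genome_id, anchor, expand_window(anchor, length, half_width))
        for anchor in anchors
    ]
    loci = merge_anchor_windows(loci)
    for locus in loci:
        ws, we = locus.window
        window_seq = sequence[ws:we]
        classification, rt_hits = classify_locus(
            window_seq, rt_ltr_profile, rt_nonltr_profile,
            target_id=f"{genome_id}:{ws}-{we}",
        )
        locus.classification = classification
        locus.rt_hits = _offset_hits(rt_hits, ws)
        if classification == INDIVIDUAL_RNH:
            locus.group = "aRNH"
            continue
        chd_present = None
        if chd_profile is not None:
            locus.chd_hits = _offset_hits(
                scan_genome(locus.genome_id, window_seq, chd_profile), ws
            )
            chd_present = bool(locus.chd_hits)
        proteins = [ft.protein for ft in translate_six_frames(window_seq)]
        locus.group = assign_group(
            proteins, references, min_identity=min_identity,
            min_ratio=min_ratio, chd_present=chd_present,
        )
    return loci


def mine_fmrnh(
    genome_id: str,
    sequence: str,
    fmrnh_profile: DomainProfile,
    flank: int = 1_000,
) -> list[CandidateLocus]:
    """Mine RT-free Fungi/Metazoa-type RNase H loci with 1 kb flanks."""
    length = len(sequence)
    anchors = scan_genome(genome_id, sequence, fmrnh_profile)
    loci = [
        CandidateLocus(
            genome_id,
            anchor,
            expand_window(anchor, length, half_width=flank),
            classification=INDIVIDUAL_RNH,
            group="fmRNH",
        )
        for anchor in anchors
    ]
    return merge_anchor_windows(loci)


def locus_category(locus: CandidateLocus) -> str:
    """Count-table column for one locus: the group for RT-associated loci,
    the clade label (or fmRNH) for individual RNHs."""
    return locus.group


def count_table(
    loci: Iterable[CandidateLocus],
    genome_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-genome element counts, RT-associated groups first, then the
    individual-RNH categories, fmRNH last. Row sums equal the number of
    classified loci per genome."""
    loci = list(loci)
    genomes = list(genome_ids) if genome_ids is not None else sorted(
        {l.genome_id for l in loci}
    )
    categories = {locus_category(l) for l in loci}
    rt_cols = list(RT_GROUPS)
    if any(l.classification != INDIVIDUAL_RNH and l.group == "unassigned" for l in loci):
        rt_cols = rt_cols + ["unassigned"]
    individual_cols = sorted(
        c for c in categories if c not in set(rt_cols) | {"fmRNH"}
    )
    columns = rt_cols + individual_cols + ["fmRNH"]
    table = pd.DataFrame(0, index=genomes, columns=columns, dtype=int)
    table.index.name = "genome"
    for locus in loci:
        table.at[locus.genome_id, locus_category(locus)] += 1
    return table


def render_count_tsv(table: pd.DataFrame, path) -> None:
    """Write the count matrix as TSV with '-' standing for zero."""
    rendered = table.astype(object).where(table != 0, "-")
    rendered.to_csv(path, sep="\t")


def loci_to_frame(loci: Iterable[CandidateLocus]) -> pd.DataFrame:
    rows = []
    for l in loci:
        gs, ge = l.anchor.genome_interval()
        rows.append(
            {
                "genome": l.genome_id,
                "anchor_profile": l.anchor.profile_name,
                "anchor_start": gs,
                "anchor_end": ge,
                "anchor_frame": l.anchor.frame,
                "anchor_score": round(l.anchor.score, 3),
                "window_start": l.window[0],
                "window_end": l.window[1],
                "classification": l.classification,
                "group": l.group,
                "n_rt_hits": len(l.rt_hits),
                "n_chd_hits": len(l.chd_hits),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "genome", "anchor_profile", "anchor_start", "anchor_end",
            "anchor_frame", "anchor_score", "window_start", "window_end",
            "classification", "group", "n_rt_hits", "n_chd_hits",
        ],
    )
    return frame.sort_values(["genome", "anchor_start"]).reset_index(drop=True)
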