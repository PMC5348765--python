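"""Position-specific domain profiles and local Viterbi search.

This module provides the domain-detection layer of the pipeline: protein
domain families (RNase H subtypes, reverse transcriptases, chromodomain,
endonucleases, integrase, protease) are modelled as position-specific
probabilistic profiles built from seed alignments, and searched against
six-frame translations of genomic DNA with a local (Smith-Waterman-style
entry/exit) Viterbi decoder over match/insert/delete states.

Scores are log-odds in bits against a background amino-acid distribution
derived from the standard genetic code (the distribution a six-frame
translation of compositionally uniform DNA produces). Stop codons ('*')
and unknown residues ('X') are emitted at background, i.e. score-neutral,
so degenerate genomic copies containing in-frame stops still produce hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from numba import njit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: code used for 'X', '*' and anything else: emitted at background (0 bits)
WILD_CODE = 20

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LOG2 = math.log(2.0)


def codon_background() -> np.ndarray:
    """Amino-acid frequencies implied by the standard code on uniform DNA.

    Each of the 61 sense codons contributes 1/61 to its amino acid. This is
    the natural null model for scoring six-frame translations of random
    nucleotide background.
    """
    counts = np.zeros(20)
    for codon, aa in _CODON_TABLE.forward_table.items():
        if aa in AA_INDEX:
            counts[AA_INDEX[aa]] += 1
    return counts / counts.sum()


BACKGROUND = codon_background()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TABLE.forward_table[codon]


class FrameMap:
    """Back-maps protein coordinates on one reading frame to forward-strand
    nucleotide intervals (0-based, half-open)."""

    def __init__(self, frame: int, seq_length: int):
        if frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {frame}")
        self.frame = frame
        self.seq_length = seq_length

    def codon_interval(self, protein_index: int) -> tuple[int, int]:
        off = abs(self.frame) - 1
        if self.frame > 0:
            start = off + 3 * protein_index
            return start, start + 3
        # reverse frames index into the reverse complement
        rc_start = off + 3 * protein_index
        return self.seq_length - rc_start - 3, self.seq_length - rc_start

    def interval(self, protein_start: int, protein_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval covered by a protein interval."""
        if protein_end <= protein_start:
            raise ValueError("empty protein interval")
        a = self.codon_interval(protein_start)
        b = self.codon_interval(protein_end - 1)
        return min(a[0], b[0]), max(a[1], b[1])


class FrameTranslation(NamedTuple):
    frame: int
    protein: str
    mapper: FrameMap


def translate_six_frames(sequence: str) -> list[FrameTranslation]:
    """Translate a DNA sequence in all six frames, stop-agnostic.

    Stop codons are emitted as '*' (the scan is frame-wise; ORF logic lives
    in :mod:`retromine.annotate`); codons containing N translate to 'X'.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty input")
    for ch in set(seq) - set("ACGTN"):
        raise ValueError(f"non-IUPAC character {ch!r} in sequence")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out: list[FrameTranslation] = []
    rc = reverse_complement(seq)
    for frame in (1, 2, 3, -1, -2, -3):
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        n_codons = (len(src) - off) // 3
        protein = "".join(
            translate_codon(src[off + 3 * i : off + 3 * i + 3]) for i in range(n_codons)
        )
        out.append(FrameTranslation(frame, protein, FrameMap(frame, len(seq))))
    return out


# ---------------------------------------------------------------------------
# Seed alignments and profiles
# ---------------------------------------------------------------------------


@dataclass
class SeedAlignment:
    """A gapped amino-acid alignment seeding one domain-family profile."""

    name: str
    rows: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("seed alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("seed alignment rows differ in length")
        allowed = set(AMINO_ACIDS + "-")
        for row in self.rows:
            bad = set(row.upper()) - allowed
            if bad:
                raise ValueError(f"invalid residue(s) {sorted(bad)} in seed alignment")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "SeedAlignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no records in {path}")
        return cls(name=name or records[0].id, rows=[str(r.seq) for r in records],
                   source=str(path))


@dataclass
class DomainProfile:
    """Position-specific log-odds model of a protein domain family.

    emissions_logodds has shape (n_states, 21); column 20 scores wildcards
    ('X', '*') at 0 bits. Transition parameters follow a Plan7-style local
    model with uniform entry over match states and free exit.
    """

    name: str
    match_columns: list[int]
    emissions: np.ndarray  # (k, 20) probabilities
    background: np.ndarray  # (20,)
    score_threshold: float
    insert_open: float = 0.01
    insert_extend: float = 0.4
    delete_open: float = 0.01
    delete_extend: float = 0.4
    catalytic_states: Optional[list[int]] = None  # match-state indices

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        k = self.emissions.shape[0]
        if k < 5:
            raise ValueError("profile needs >= 5 match states")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-state emission probabilities must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    # -- derived scoring arrays --------------------------------------------

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    @property
    def emissions_logodds(self) -> np.ndarray:
        """(k, 21) log-odds in bits; wildcard column is 0."""
        lo = np.log2(self.emissions / self.background[None, :])
        return np.hstack([lo, np.zeros((lo.shape[0], 1))])

    @property
    def transitions(self) -> dict[str, float]:
        """Transition scores in bits."""
        mi, me = self.insert_open, self.insert_extend
        do, de = self.delete_open, self.delete_extend
        return {
            "MM": math.log2(1.0 - mi - do),
            "MI": math.log2(mi),
            "MD": math.log2(do),
            "II": math.log2(me),
            "IM": math.log2(1.0 - me),
            "DD": math.log2(de),
            "DM": math.log2(1.0 - de),
        }

    @property
    def entry_score(self) -> float:
        """Uniform local entry over match states, in bits."""
        return -math.log2(self.n_states)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.emissions, axis=1))

    def max_score(self) -> float:
        """Maximum attainable local alignment score, in bits.

        Best over contiguous match-state runs of per-state best emissions
        chained with match-match transitions (Kadane over maxe + tMM).
        """
        maxe = self.emissions_logodds[:, :20].max(axis=1)
        tmm = self.transitions["MM"]
        vals = maxe + tmm
        best = run = -math.inf
        for v in vals:
            run = v if run < 0 else run + v
            best = max(best, run)
        return self.entry_score - tmm + best

    # -- plain-text persistence --------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# profile\t{self.name}\n")
            fh.write(f"# n_states\t{self.n_states}\n")
            fh.write("# match_columns\t" + ",".join(map(str, self.match_columns)) + "\n")
            fh.write("# background\t" + ",".join(f"{b:.10g}" for b in self.background) + "\n")
            fh.write(
                "# transitions\t"
                f"{self.insert_open:.10g},{self.insert_extend:.10g},"
                f"{self.delete_open:.10g},{self.delete_extend:.10g}\n"
            )
            fh.write(f"# score_threshold\t{self.score_threshold:.10g}\n")
            if self.catalytic_states is not None:
                fh.write("# catalytic_states\t" + ",".join(map(str, self.catalytic_states)) + "\n")
            fh.write("state\t" + "\t".join(AMINO_ACIDS) + "\n")
            for j in range(self.n_states):
                fh.write(str(j) + "\t" + "\t".join(f"{p:.10g}" for p in self.emissions[j]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DomainProfile":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("\t")
                    meta[key.strip()] = value
                elif not line.startswith("state"):
                    rows.append([float(x) for x in line.split("\t")[1:]])
        io_, ie, do, de = (float(x) for x in meta["transitions"].split(","))
        cat = meta.get("catalytic_states")
        return cls(
            name=meta["profile"],
            match_columns=[int(x) for x in meta["match_columns"].split(",")],
            emissions=np.array(rows),
            background=np.array([float(x) for x in meta["background"].split(",")]),
            score_threshold=float(meta["score_threshold"]),
            insert_open=io_, insert_extend=ie, delete_open=do, delete_extend=de,
            catalytic_states=[int(x) for x in cat.split(",")] if cat else None,
        )


def build_profile(
    seed: SeedAlignment,
    gap_fraction_cutoff: float = 0.5,
    pseudocount: float = 1.0,
    score_threshold: float | None = None,
    background: np.ndarray | None = None,
    catalytic_columns: Sequence[int] | None = None,
    **transition_params,
) -> DomainProfile:
    """Estimate a profile from a seed alignment.

    Columns with gap fraction < ``gap_fraction_cutoff`` become match states;
    emissions are (counts + pseudocount * background) / (n_rows + pseudocount).
    When ``score_threshold`` is None it is calibrated per profile as
    max(15, 0.25 * max attainable score) — high enough that random
    excursions over megabase-scale six-frame scans stay below it, while
    heavily diverged and even frameshift-split true copies score far above.
    ``catalytic_columns`` are alignment column indices of the five active
    site positions; they are stored as match-state indices.
    """
    bg = BACKGROUND if background is None else np.asarray(background, float)
    n_rows = len(seed.rows)
    match_cols = [
        c
        for c in range(seed.n_columns)
        if sum(r[c] == "-" for r in seed.rows) / n_rows < gap_fraction_cutoff
    ]
    if not match_cols:
        raise ValueError("no match states")
    emissions = np.zeros((len(match_cols), 20))
    for j, c in enumerate(match_cols):
        counts = np.zeros(20)
        for r in seed.rows:
            if r[c] != "-":
                counts[AA_INDEX[r[c]]] += 1
        emissions[j] = (counts + pseudocount * bg) / (counts.sum() + pseudocount)
    cat_states = None
    if catalytic_columns is not None:
        col_to_state = {c: j for j, c in enumerate(match_cols)}
        cat_states = [col_to_state[c] for c in catalytic_columns]
    profile = DomainProfile(
        name=seed.name,
        match_columns=match_cols,
        emissions=emissions,
        background=bg,
        score_threshold=0.0,
        catalytic_states=cat_states,
        **transition_params,
    )
    if score_threshold is None:
        score_threshold = max(15.0, 0.25 * profile.max_score())
    profile.score_threshold = float(score_threshold)
    return profile


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

NEG = -1e30


def encode_protein(protein: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, WILD_CODE) for ch in protein.upper()], dtype=np.int64)


@njit(cache=True)
def _viterbi_best(codes, emis, tmm, tmi, tmd, tim, tii, tdm, tdd, entry):  # pragma: no cover
    """Score-only local Viterbi; returns (best score, start, end) of the best
    local hit with ties broken by smaller start (then first-found end)."""
    n = codes.shape[0]
    k = emis.shape[0]
    prevM = np.full(k, NEG)
    prevI = np.full(k, NEG)
    prevD = np.full(k, NEG)
    sprevM = np.zeros(k, np.int64)
    sprevI = np.zeros(k, np.int64)
    sprevD = np.zeros(k, np.int64)
    curM = np.full(k, NEG)
    curI = np.full(k, NEG)
    curD = np.full(k, NEG)
    scurM = np.zeros(k, np.int64)
    scurI = np.zeros(k, np.int64)
    scurD = np.zeros(k, np.int64)
    best = NEG
    best_start = -1
    best_end = -1
    for i in range(1, n + 1):
        c = codes[i - 1]
        for j in range(k):
            # match: entry > diag-M > diag-I > diag-D (strict > keeps order)
            sc = entry
            st = i - 1
            if j > 0:
                v = prevM[j - 1] + tmm
                if v > sc:
                    sc = v
                    st = sprevM[j - 1]
                v = prevI[j - 1] + tim
                if v > sc:
                    sc = v
                    st = sprevI[j - 1]
                v = prevD[j - 1] + tdm
                if v > sc:
                    sc = v
                    st = sprevD[j - 1]
            m = sc + emis[j, c]
            curM[j] = m
            scurM[j] = st
            # insert (emits at background: +0)
            a = prevM[j] + tmi
            b = prevI[j] + tii
            if a >= b:
                curI[j] = a
                scurI[j] = sprevM[j]
            else:
                curI[j] = b
                scurI[j] = sprevI[j]
            # delete (within current row)
            if j > 0:
                a = curM[j - 1] + tmd
                b = curD[j - 1] + tdd
                if a >= b:
                    curD[j] = a
                    scurD[j] = scurM[j - 1]
                else:
                    curD[j] = b
                    scurD[j] = scurD[j - 1]
            else:
                curD[j] = NEG
                scurD[j] = 0
            # exit is free from any match state
            if m > best or (m == best and st < best_start):
                best = m
                best_start = st
                best_end = i
        prevM, curM = curM, prevM
        prevI, curI = curI, prevI
        prevD, curD = curD, prevD
        sprevM, scurM = scurM, sprevM
        sprevI, scurI = scurI, sprevI
        sprevD, scurD = scurD, sprevD
    return best, best_start, best_end


@njit(cache=True)
def _viterbi_full(codes, emis, tmm, tmi, tmd, tim, tii, tdm, tdd, entry):  # pragma: no cover
    """Dense local Viterbi with back-pointers for trace reconstruction.

    Pointer codes: 0 entry/stop, 1 from M, 2 from I, 3 from D.
    """
    n = codes.shape[0]
    k = emis.shape[0]
    M = np.full((n + 1, k), NEG)
    I = np.full((n + 1, k), NEG)
    D = np.full((n + 1, k), NEG)
    SM = np.zeros((n + 1, k), np.int64)
    SI = np.zeros((n + 1, k), np.int64)
    SD = np.zeros((n + 1, k), np.int64)
    PM = np.zeros((n + 1, k), np.int8)
    PI = np.zeros((n + 1, k), np.int8)
    PD = np.zeros((n + 1, k), np.int8)
    for i in range(1, n + 1):
        c = codes[i - 1]
        for j in range(k):
            sc = entry
            st = i - 1
            ptr = 0
            if j > 0:
                v = M[i - 1, j - 1] + tmm
                if v > sc:
                    sc, st, ptr = v, SM[i - 1, j - 1], 1
                v = I[i - 1, j - 1] + tim
                if v > sc:
                    sc, st, ptr = v, SI[i - 1, j - 1], 2
                v = D[i - 1, j - 1] + tdm
                if v > sc:
                    sc, st, ptr = v, SD[i - 1, j - 1], 3
            M[i, j] = sc + emis[j, c]
            SM[i, j] = st
            PM[i, j] = ptr
            a = M[i - 1, j] + tmi
            b = I[i - 1, j] + tii
            if a >= b:
                I[i, j] = a
                SI[i, j] = SM[i - 1, j]
                PI[i, j] = 1
            else:
                I[i, j] = b
                SI[i, j] = SI[i - 1, j]
                PI[i, j] = 2
            if j > 0:
                a = M[i, j - 1] + tmd
                b = D[i, j - 1] + tdd
                if a >= b:
                    D[i, j] = a
                    SD[i, j] = SM[i, j - 1]
                    PD[i, j] = 1
                else:
                    D[i, j] = b
                    SD[i, j] = SD[i, j - 1]
                    PD[i, j] = 3
    return M, I, D, SM, PM, PI, PD


@dataclass
class DomainHit:
    """A scored local match of a profile on a (translated) protein."""

    profile_name: str
    target_id: str
    frame: int  # {+1,+2,+3,-1,-2,-3} or 0 for plain protein input
    protein_start: int
    protein_end: int
    score: float
    genome_start: Optional[int] = None
    genome_end: Optional[int] = None
    aligned_state_path: list[tuple[str, int, Optional[int]]] = field(default_factory=list)
    matched_protein: str = ""

    def genome_interval(self) -> tuple[int, int]:
        if self.genome_start is None or self.genome_end is None:
            raise ValueError("hit has no genome coordinates")
        return self.genome_start, self.genome_end


def _scoring_args(profile: DomainProfile):
    t = profile.transitions
    return (
        profile.emissions_logodds,
        t["MM"], t["MI"], t["MD"], t["IM"], t["II"], t["DM"], t["DD"],
        profile.entry_score,
    )


def _traceback(profile: DomainProfile, codes: np.ndarray, offset: int):
    """Best local path within ``codes``; returns (score, start, end, path).

    Cell selection mirrors the comparison order of the score-only kernel so
    both report the same optimum.
    """
    args = _scoring_args(profile)
    M, I, D, SM, PM, PI, PD = _viterbi_full(codes, *args)
    n, k = codes.shape[0], profile.n_states
    best = NEG
    bi = bj = bst = -1
    for i in range(1, n + 1):
        for j in range(k):
            m = M[i, j]
            st = SM[i, j]
            if m > best or (m == best and st < bst):
                best, bst, bi, bj = m, st, i, j
    path: list[tuple[str, int, Optional[int]]] = []
    i, j, state = bi, bj, "M"
    while True:
        if state == "M":
            path.append(("M", j, offset + i - 1))
            ptr = PM[i, j]
            if ptr == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[ptr]
            i, j = i - 1, j - 1
        elif state == "I":
            path.append(("I", j, offset + i - 1))
            state = {1: "M", 2: "I"}[PI[i, j]]
            i = i - 1
        else:
            path.append(("D", j, None))
            state = {1: "M", 3: "D"}[PD[i, j]]
            j = j - 1
    path.reverse()
    return float(best), offset + bst, offset + bi, path


def viterbi_search(
    profile: DomainProfile,
    protein: str,
    target_id: str = "",
    frame: int = 0,
    threshold: float | None = None,
    mapper: FrameMap | None = None,
) -> list[DomainHit]:
    """All non-overlapping local hits with score >= threshold.

    Hits are found greedily best-first: the best hit is reported, its span
    excluded, and the flanking segments searched recursively (equivalent to
    masking, since no local path can cross an excluded residue). Returned
    sorted by start; fully deterministic.
    """
    thr = profile.score_threshold if threshold is None else threshold
    codes = encode_protein(protein)
    if codes.size == 0:
        return []
    args = _scoring_args(profile)
    spans: list[tuple[int, int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        score, st, en = _viterbi_best(codes[lo:hi], *args)
        if score < thr or st < 0:
            return
        spans.append((lo + st, lo + en, score))
        recurse(lo, lo + st)
        recurse(lo + en, hi)

    recurse(0, codes.size)
    spans.sort()
    hits = []
    for st, en, score in spans:
        _, pst, pen, path = _traceback(profile, codes[st:en], st)
        hit = DomainHit(
            profile_name=profile.name,
            target_id=target_id,
            frame=frame,
            protein_start=st,
            protein_end=en,
            score=round(score, 6),
            aligned_state_path=path,
            matched_protein=protein[st:en],
        )
        if mapper is not None:
            hit.genome_start, hit.genome_end = mapper.interval(st, en)
        hits.append(hit)
    return hits


def brute_force_best_score(profile: DomainProfile, protein: str) -> float:
    """Independent oracle: exhaustive enumeration of all local state paths.

    Exponential; intended for profiles with <= ~6 states and targets of
    <= ~10 residues. Shares only the model definition with the DP decoder.
    """
    codes = encode_protein(protein)
    emis = profile.emissions_logodds
    t = profile.transitions
    entry = profile.entry_score
    n, k = codes.size, profile.n_states
    best = [NEG]

    def walk(state: str, j: int, i: int, score: float) -> None:
        # i = number of residues consumed so far (index of the next residue)
        if state == "M":
            best[0] = max(best[0], score)
            if i < n:
                walk("I", j, i + 1, score + t["MI"])
            if j + 1 < k:
                if i < n:
                    walk("M", j + 1, i + 1, score + t["MM"] + emis[j + 1, codes[i]])
                walk("D", j + 1, i, score + t["MD"])
        elif state == "I":
            if i < n:
                walk("I", j, i + 1, score + t["II"])
            if j + 1 < k and i < n:
                walk("M", j + 1, i + 1, score + t["IM"] + emis[j + 1, codes[i]])
        else:  # D
            if j + 1 < k:
                walk("D", j + 1, i, score + t["DD"])
                if i < n:
                    walk("M", j + 1, i + 1, score + t["DM"] + emis[j + 1, codes[i]])

    for start in range(n):
        for j0 in range(k):
            walk("M", j0, start + 1, entry + emis[j0, codes[start]])
    return best[0]


# ---------------------------------------------------------------------------
# Genome scanning
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def dedupe_hits(hits: Iterable[DomainHit], min_overlap: float = 0.5) -> list[DomainHit]:
    """Reduce hits overlapping > min_overlap reciprocally (genome coords)
    to the best-scoring one. Deterministic: score desc, then position."""
    ranked = sorted(hits, key=lambda h: (-h.score, h.genome_start, h.genome_end, h.frame))
    kept: list[DomainHit] = []
    for hit in ranked:
        iv = hit.genome_interval()
        if all(_reciprocal_overlap(iv, k.genome_interval()) <= min_overlap for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.genome_start, h.genome_end, h.frame))
    return kept


def scan_genome(
    target_id: str,
    sequence: str,
    profile: DomainProfile,
    threshold: float | None = None,
) -> list[DomainHit]:
    """Search all six reading frames; hits carry genome coordinates and
    cross-frame duplicates (>50% reciprocal genome overlap) are reduced to
    the best-scoring hit."""
    all_hits: list[DomainHit] = []
    for frame, protein, mapper in translate_six_frames(sequence):
        all_hits.extend(
            viterbi_search(profile, protein, target_id=target_id, frame=frame,
                           threshold=threshold, mapper=mapper)
        )
    return dedupe_hits(all_hits)


def write_hits_tsv(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tprofile\tframe\tgenome_start\tgenome_end\tscore\n")
        for h in hits:
            gs = "" if h.genome_start is None else h.genome_start
            ge = "" if h.genome_end is None else h.genome_end
            fh.write(f"{h.target_id}\t{h.profile_name}\t{h.frame}\t{gs}\t{ge}\t{h.score:.3f}\n")
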