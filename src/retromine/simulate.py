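"""Synthetic genomes with planted, divergence-controlled retroelements.

The generator emulates the study system: genome assemblies containing
degenerate copies of four aRNH-carrying element architectures —

* ``Chronos``  LTR retrotransposon, pol = PR-RT-gRH-aRH-IN-CHD (dual RNase H,
  chromodomain fused after the integrase);
* ``Archon``   LTR retrotransposon, pol = PR-RT-gRH-aRH-IN (dual RNase H,
  no chromodomain);
* ``L1``       non-LTR retrotransposon, ORF2 = EN-RT-CCHC-aRH with the aRNH
  C-terminal and the CCHC zinc knuckle upstream of it;
* ``Utopia``   non-LTR retrotransposon, single ORF RT-aRH-RLE (domain order
  within the ORF is an explicit assumption of the generator);

plus RT-free cellular genes: a lone aRNH ORF and a lone fmRNH ORF.

All protein templates are synthetic: generated once from a fixed internal
seed with the canonical motifs embedded (D-E-D-R-D active site for aRNH,
D-E-D-H-D for fmRNH, a CCHC zinc knuckle, a YxDD-like RT motif), so audit
operations have exact expectations and nothing is copied from licensed
repeat databases. Each element group carries its own aRNH and RT variants,
derived once from the base templates at ~25% amino-acid divergence with the
active site protected — this is what gives the simulated data the per-group
clade structure the downstream phylogenetics is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import AMINO_ACIDS, BACKGROUND, SeedAlignment, reverse_complement

_TEMPLATE_SEED = 490817  # fixed: templates are constants of the package

#: length (aa) of each base domain family template
DOMAIN_LENGTHS = {
    "PR": 100,
    "RT_LTR": 250,
    "RT_nonLTR": 250,
    "gRNH": 130,
    "aRNH": 150,
    "fmRNH": 150,
    "INT": 180,
    "CHD": 60,
    "EN": 180,
    "RLE": 120,
}

#: five active-site positions (0-based, within the domain) and the canonical
#: residues audited per RNase H subtype; site 4 is the semiconservative
#: position: R in aRNH, H in fmRNH, unconstrained in the Ty3/Gypsy gRNH
CATALYTIC_POSITIONS = {
    "aRNH": ([9, 48, 69, 109, 132], "DEDRD"),
    "fmRNH": ([9, 48, 69, 109, 132], "DEDHD"),
    "gRNH": ([8, 40, 60, 95, 118], "DEDVD"),
}

#: CCHC zinc knuckle: C-x(2)-C-x(4)-H-x(4)-C
CCHC_MOTIF = "CAQCGKPGHTARQC"

_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT  # noqa: E402

for _codon, _aa in _CT.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


@dataclass(frozen=True)
class DomainTemplate:
    name: str
    family: str  # base family (profile) this template is detected by
    protein: str
    catalytic: Optional[tuple[int, ...]] = None  # positions within protein

    def __len__(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class Feature:
    label: str
    start: int  # nt, 0-based half-open within the element
    end: int


@dataclass(frozen=True)
class ElementTemplate:
    group: str
    nt: str
    features: tuple[Feature, ...]
    orf_proteins: dict[str, str] = field(default_factory=dict, hash=False)

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def domain_nt_positions(self, label: str, protein_positions: Sequence[int],
                            orf_label: str) -> list[int]:
        """First-nt positions (element coords) of codons for given positions
        within the named domain feature."""
        dom = self.feature(label)
        return [dom.start + 3 * p for p in protein_positions]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND))


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _with_residues(protein: str, positions: Sequence[int], residues: str) -> str:
    chars = list(protein)
    for pos, res in zip(positions, residues):
        chars[pos] = res
    return "".join(chars)


def _variant(rng: np.random.Generator, protein: str, divergence: float,
             protect: Sequence[int] = ()) -> str:
    """Substitution-only amino-acid variant at the given divergence."""
    protected = set(protect)
    chars = list(protein)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < divergence:
            alternatives = [a for a in AMINO_ACIDS if a != chars[i]]
            chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def backtranslate(rng: np.random.Generator, protein: str) -> str:
    """Nucleotide sequence encoding ``protein``, synonymous codons uniform."""
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


@lru_cache(maxsize=1)
def default_domain_templates() -> dict[str, DomainTemplate]:
    """The package's fixed set of domain templates (base families plus
    per-group aRNH/RT variants). Deterministic: built from an internal seed."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    templates: dict[str, DomainTemplate] = {}
    for family, length in DOMAIN_LENGTHS.items():
        protein = _random_protein(rng, length)
        catalytic = None
        if family in CATALYTIC_POSITIONS:
            positions, residues = CATALYTIC_POSITIONS[family]
            protein = _with_residues(protein, positions, residues)
            catalytic = tuple(positions)
        if family == "RT_LTR":
            protein = _with_residues(protein, [150, 151, 152, 153], "YVDD")
        if family == "RT_nonLTR":
            protein = _with_residues(protein, [150, 151, 152, 153], "YADD")
        templates[family] = DomainTemplate(family, family, protein, catalytic)

    arnh = templates["aRNH"]
    for group in ("Chronos", "Archon", "L1", "Utopia", "cellular"):
        protein = _variant(rng, arnh.protein, 0.25, protect=arnh.catalytic)
        templates[f"aRNH_{group}"] = DomainTemplate(
            f"aRNH_{group}", "aRNH", protein, arnh.catalytic
        )
    rt_motif = tuple(range(150, 154))
    for group in ("Chronos", "Archon"):
        protein = _variant(rng, templates["RT_LTR"].protein, 0.25, protect=rt_motif)
        templates[f"RT_LTR_{group}"] = DomainTemplate(f"RT_LTR_{group}", "RT_LTR", protein)
    for group in ("L1", "Utopia"):
        protein = _variant(rng, templates["RT_nonLTR"].protein, 0.25, protect=rt_motif)
        templates[f"RT_nonLTR_{group}"] = DomainTemplate(
            f"RT_nonLTR_{group}", "RT_nonLTR", protein
        )
    return templates


_LINKER = "GSGSG"


def _build_orf(rng: np.random.Generator, parts: list[tuple[str, str]],
               orf_start_nt: int) -> tuple[str, str, list[Feature]]:
    """Assemble an ORF from (label, protein) parts joined by linkers.

    Returns (orf_nt including ATG and stop, orf protein, domain features in
    element coordinates given the ORF's nt start).
    """
    protein = "M"
    feats: list[Feature] = []
    for idx, (label, part) in enumerate(parts):
        if idx > 0:
            protein += _LINKER
        if label:
            aa_start = len(protein)
            feats.append(
                Feature(label, orf_start_nt + 3 * aa_start,
                        orf_start_nt + 3 * (aa_start + len(part)))
            )
        protein += part
    body = backtranslate(rng, protein[1:])  # M encoded by ATG below
    orf_nt = "ATG" + body + "TAA"
    return orf_nt, protein, feats


@lru_cache(maxsize=1)
def default_element_templates() -> dict[str, ElementTemplate]:
    """Element templates for the four groups and the two cellular genes."""
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    dom = default_domain_templates()
    out: dict[str, ElementTemplate] = {}

    def ltr_element(group: str, with_chd: bool) -> ElementTemplate:
        ltr = _random_dna(rng, 300)
        gag = _random_protein(rng, 249)
        pos = 0
        features: list[Feature] = []
        parts: list[str] = []

        def add(seq: str, label: str | None = None):
            nonlocal pos
            if label:
                features.append(Feature(label, pos, pos + len(seq)))
            parts.append(seq)
            pos += len(seq)

        add(ltr, "LTR5")
        add(_random_dna(rng, 40))
        orf1_nt, orf1_protein, _ = _build_orf(rng, [("", gag)], pos)
        add(orf1_nt, "ORF1")
        add(_random_dna(rng, 30))
        pol_parts = [
            ("PR", dom["PR"].protein),
            ("RT_LTR", dom[f"RT_LTR_{group}"].protein),
            ("gRNH", dom["gRNH"].protein),
            ("aRNH", dom[f"aRNH_{group}"].protein),
            ("INT", dom["INT"].protein),
        ]
        if with_chd:
            pol_parts.append(("CHD", dom["CHD"].protein))
        orf2_nt, orf2_protein, domain_feats = _build_orf(rng, pol_parts, pos)
        add(orf2_nt, "ORF2")
        features.extend(domain_feats)
        add(_random_dna(rng, 40))
        add(ltr, "LTR3")
        return ElementTemplate(group, "".join(parts), tuple(features),
                               {"ORF1": orf1_protein, "ORF2": orf2_protein})

    out["Chronos"] = ltr_element("Chronos", with_chd=True)
    out["Archon"] = ltr_element("Archon", with_chd=False)

    # L1: ORF1 + ORF2 = EN-RT-CCHC-aRH, aRNH C-terminal, CCHC upstream of it
    pos = 0
    features = []
    parts = []

    def add(seq: str, label: str | None = None):
        nonlocal pos
        if label:
            features.append(Feature(label, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)

    add(_random_dna(rng, 25))
    orf1_nt, orf1_protein, _ = _build_orf(rng, [("", _random_protein(rng, 199))], pos)
    add(orf1_nt, "ORF1")
    add(_random_dna(rng, 30))
    cchc_region = "GSRA" + CCHC_MOTIF + _random_protein(rng, 12)
    orf2_nt, orf2_protein, domain_feats = _build_orf(
        rng,
        [
            ("EN", dom["EN"].protein),
            ("RT_nonLTR", dom["RT_nonLTR_L1"].protein),
            ("CCHC", cchc_region),
            ("aRNH", dom["aRNH_L1"].protein),
        ],
        pos,
    )
    add(orf2_nt, "ORF2")
    features.extend(domain_feats)
    add(_random_dna(rng, 25))
    out["L1"] = ElementTemplate("L1", "".join(parts), tuple(features),
                                {"ORF1": orf1_protein, "ORF2": orf2_protein})

    # Utopia: single ORF RT-aRH-RLE
    pos = 0
    features = []
    parts = []
    add(_random_dna(rng, 25))
    orf_nt, orf_protein, domain_feats = _build_orf(
        rng,
        [
            ("RT_nonLTR", dom["RT_nonLTR_Utopia"].protein),
            ("aRNH", dom["aRNH_Utopia"].protein),
            ("RLE", dom["RLE"].protein),
        ],
        pos,
    )
    add(orf_nt, "ORF2")
    features.extend(domain_feats)
    add(_random_dna(rng, 25))
    out["Utopia"] = ElementTemplate("Utopia", "".join(parts), tuple(features),
                                    {"ORF2": orf_protein})

    # cellular RNase H genes: a lone ORF each
    for gene, tmpl_name, label in (
        ("aRNH_gene", "aRNH_cellular", "aRNH"),
        ("fmRNH_gene", "fmRNH", "fmRNH"),
    ):
        pos = 0
        features = []
        parts = []
        add(_random_dna(rng, 15))
        orf_nt, orf_protein, domain_feats = _build_orf(
            rng, [(label, dom[tmpl_name].protein)], pos
        )
        add(orf_nt, "ORF")
        features.extend(domain_feats)
        add(_random_dna(rng, 15))
        out[gene] = ElementTemplate(gene, "".join(parts), tuple(features),
                                    {"ORF": orf_protein})
    return out


# ---------------------------------------------------------------------------
# Seed alignments and references for the other modules
# ---------------------------------------------------------------------------


def seed_alignment(family: str, n_copies: int = 10, divergence: float = 0.08,
                   seed: int | None = None) -> SeedAlignment:
    """Substitution-only seed alignment for one base domain family, derived
    from the family template (trivially aligned: equal lengths, no gaps)."""
    tmpl = default_domain_templates()[family]
    rng = np.random.default_rng(_TEMPLATE_SEED + 1000 if seed is None else seed)
    rows = [tmpl.protein]
    protect = tmpl.catalytic or ()
    for _ in range(n_copies - 1):
        rows.append(_variant(rng, tmpl.protein, divergence, protect=protect))
    return SeedAlignment(name=family, rows=rows, source="synthetic template family")


def default_seed_alignments() -> dict[str, SeedAlignment]:
    return {family: seed_alignment(family) for family in DOMAIN_LENGTHS}


def group_references() -> dict[str, str]:
    """Representative pol/ORF2 proteins used for group assignment."""
    elements = default_element_templates()
    return {g: elements[g].orf_proteins["ORF2"] for g in ("Chronos", "Archon", "L1", "Utopia")}


def arnh_domain_references() -> dict[str, str]:
    """Per-group aRNH domain proteins (phylo clade references)."""
    dom = default_domain_templates()
    return {g: dom[f"aRNH_{g}"].protein for g in ("Chronos", "Archon", "L1", "Utopia")}


# ---------------------------------------------------------------------------
# Mutation and genome assembly
# ---------------------------------------------------------------------------


@dataclass
class PlantedTruth:
    """Ground truth for one planted insertion (genome coordinates)."""

    genome_id: str
    start: int
    end: int
    strand: str
    group: str
    divergence: float
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def domain_interval(self, label: str) -> tuple[int, int]:
        for lab, s, e in self.domains:
            if lab == label:
                return s, e
        raise KeyError(label)


def mutate_copy(
    template_nt: str,
    nucleotide_divergence: float,
    indel_rate: float,
    rng: np.random.Generator | int,
    protect: Iterable[tuple[int, int]] = (),
    force_positions: Iterable[int] = (),
) -> tuple[str, np.ndarray]:
    """Degenerate copy of a template with a template->copy coordinate map.

    Substitutions are uniform over unprotected sites at the stated rate;
    indels of length 1-3 occur at ``indel_rate`` per site. ``protect``
    intervals (e.g. catalytic codons) are exempt from all mutation;
    ``force_positions`` receive a guaranteed substitution (used to build
    targeted active-site knockouts). Returns (copy, pos_map) where
    pos_map[i] is the copy coordinate of template position i
    (pos_map has length len(template)+1).
    """
    if not 0.0 <= nucleotide_divergence <= 0.5:
        raise ValueError("divergence must be within [0, 0.5]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    protected = np.zeros(len(template_nt), dtype=bool)
    for s, e in protect:
        protected[s:e] = True
    forced = set(force_positions)
    bases = "ACGT"
    out: list[str] = []
    pos_map = np.empty(len(template_nt) + 1, dtype=np.int64)
    skip = 0
    for i, base in enumerate(template_nt):
        pos_map[i] = len(out)
        if skip > 0:
            skip -= 1
            continue
        if not protected[i]:
            if i in forced or rng.random() < nucleotide_divergence:
                alternatives = [b for b in bases if b != base]
                base = alternatives[rng.integers(3)]
        out.append(base)
        if indel_rate > 0 and not protected[i] and rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                out.extend(rng.choice(list(bases), size=length))
            else:
                skip = length
    pos_map[len(template_nt)] = len(out)
    return "".join(out), pos_map


@dataclass(frozen=True)
class PlantSpec:
    """One line of a genome plan: plant ``count`` copies of ``group`` at the
    given nucleotide divergence (and optional indel rate)."""

    group: str
    count: int
    divergence: float
    indel_rate: float = 0.0


def build_genome(
    plan: Sequence[PlantSpec | tuple],
    background_length: int,
    gc: float = 0.5,
    seed: int | np.random.Generator = 0,
    genome_id: str = "genome",
    min_spacing: int = 12_000,
    protect_catalytic: bool = True,
) -> tuple[str, list[PlantedTruth]]:
    """Background DNA with planted element copies and full ground truth.

    Elements are placed uniformly along the background, on a random strand,
    never overlapping; a minimum spacing (default 12 kb, i.e. wider than the
    mining window half-width) keeps the ground-truth classification of each
    insertion well defined — without it a cellular RNH gene could fall
    inside a retrotransposon's +/-10 kb window, where "no RT nearby" is no
    longer true of the locus. The final genome length is background_length
    plus the planted lengths. Same seed => byte-identical output.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    plan = [p if isinstance(p, PlantSpec) else PlantSpec(*p) for p in plan]
    elements = default_element_templates()
    copies: list[tuple[str, float, str, np.ndarray, str]] = []
    for spec in plan:
        template = elements[spec.group]
        protect = []
        if protect_catalytic:
            dom_templates = default_domain_templates()
            for feat in template.features:
                cat = CATALYTIC_POSITIONS.get(feat.label)
                if cat is not None:
                    for p in cat[0]:
                        start = feat.start + 3 * p
                        protect.append((start, start + 3))
        for _ in range(spec.count):
            copy, pos_map = mutate_copy(template.nt, spec.divergence,
                                        spec.indel_rate, rng, protect=protect)
            strand = "+" if rng.random() < 0.5 else "-"
            copies.append((spec.group, spec.divergence, copy, pos_map, strand))

    k = len(copies)
    total_planted = sum(len(c[2]) for c in copies)
    if k > 0:
        slack = background_length - (k - 1) * min_spacing - 200
        if slack <= 0 or total_planted >= background_length:
            raise ValueError("infeasible packing: background too short for plan")
        offsets = np.sort(rng.integers(0, slack, size=k))
        offsets = offsets + np.arange(k) * min_spacing + 100
        order = rng.permutation(k)
    else:
        offsets = np.array([], dtype=int)
        order = np.array([], dtype=int)

    background = _random_dna(rng, background_length, gc=gc)
    pieces: list[str] = []
    truth: list[PlantedTruth] = []
    cursor = 0
    grown = 0
    for slot, copy_idx in enumerate(order):
        group, divergence, copy, pos_map, strand = copies[copy_idx]
        x = int(offsets[slot])
        pieces.append(background[cursor:x])
        gstart = x + grown
        placed = copy if strand == "+" else reverse_complement(copy)
        pieces.append(placed)
        template = elements[group]
        domains = []
        for feat in template.features:
            cs, ce = int(pos_map[feat.start]), int(pos_map[feat.end])
            if ce <= cs:
                continue
            if strand == "+":
                domains.append((feat.label, gstart + cs, gstart + ce))
            else:
                domains.append((feat.label, gstart + len(copy) - ce,
                                gstart + len(copy) - cs))
        domains.sort(key=lambda d: (d[1], d[2], d[0]))
        truth.append(PlantedTruth(genome_id, gstart, gstart + len(copy), strand,
                                  group, divergence, domains))
        grown += len(copy)
        cursor = x
    pieces.append(background[cursor:])
    truth.sort(key=lambda t: t.start)
    return "".join(pieces), truth


# ---------------------------------------------------------------------------
# Scoring predictions against planted truth
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    precision: float
    recall: float
    n_predictions: int
    n_truth: int
    n_matched: int
    precision_defined: bool
    confusion: pd.DataFrame
    matches: list[tuple[int, int]] = field(default_factory=list)

    @property
    def label_accuracy(self) -> float:
        """Fraction of matched pairs whose labels agree."""
        if not self.n_matched:
            return float("nan")
        diag = sum(
            self.confusion.at[lab, lab]
            for lab in self.confusion.index
            if lab in self.confusion.columns
        )
        return diag / self.n_matched


def _interval_reciprocal(a, b) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def evaluate(
    predictions: Sequence[tuple[str, int, int, str]],
    truth: Sequence[tuple[str, int, int, str]],
    min_reciprocal: float = 0.5,
) -> EvalResult:
    """Match predictions to truth records by reciprocal interval overlap.

    Both inputs are (genome_id, start, end, label) tuples. A prediction
    matches a truth record when their intervals (same genome) overlap
    reciprocally >= ``min_reciprocal``; matching is greedy one-to-one by
    decreasing overlap. With zero predictions precision is undefined and
    reported as 1.0 with ``precision_defined=False``.
    """
    candidates = []
    for pi, (pg, ps, pe, _) in enumerate(predictions):
        for ti, (tg, ts, te, _) in enumerate(truth):
            if pg != tg:
                continue
            ov = _interval_reciprocal((ps, pe), (ts, te))
            if ov >= min_reciprocal:
                candidates.append((-ov, pi, ti))
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti))
    truth_labels = sorted({t[3] for t in truth})
    pred_labels = sorted({predictions[pi][3] for pi, _ in matches} | set(truth_labels))
    confusion = pd.DataFrame(0, index=truth_labels, columns=pred_labels, dtype=int)
    for pi, ti in matches:
        confusion.at[truth[ti][3], predictions[pi][3]] += 1
    n_matched = len(matches)
    precision_defined = len(predictions) > 0
    precision = n_matched / len(predictions) if precision_defined else 1.0
    recall = n_matched / len(truth) if truth else 1.0
    return EvalResult(
        precision=precision,
        recall=recall,
        n_predictions=len(predictions),
        n_truth=len(truth),
        n_matched=n_matched,
        precision_defined=precision_defined,
        confusion=confusion,
        matches=sorted(matches),
    )
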