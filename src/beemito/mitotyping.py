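"""Structural typing of tRNAleu-cox2 amplicons.

The classifier locates the region's elements by template alignment (so
amplicons of different absolute lengths can be typed with one code path),
determines the P-element form from the placement of large alignment gaps,
counts tandem Q copies, reads the DraI (TTTAAA) site configuration, and from
these assigns the maternal evolutionary lineage (A/M/C/Y), African
sub-lineage (AI/AII/AIII/Z) and element length pattern (e.g. ``P0QQ``).
Haplotype names are then called against the reference catalog by comparing
master-alignment edit lists; unmatched sequences are coined new names
following the family-base + letter-suffix convention.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import edlib

from . import grammar
from .refdata import Edit, HaplotypeCatalog, HaplotypeRecord

#: minimum fraction of identical bases for anchor (tRNAleu/cox2) matches
ANCHOR_MIN_IDENTITY = 0.80
#: minimum identity for each tandem Q repeat match
Q_MIN_IDENTITY = 0.90
#: alignment gaps at least this long count as "large" (P-form diagnostics)
LARGE_GAP_MIN = 10
#: tolerance on the expected large-deletion lengths (13/15/18 bp)
GAP_LEN_TOL = 2
#: a tRNAleu-cox2 spacer shorter than this cannot hold any P form
MIN_P_REGION = 25

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class UnrecognizedAmplicon(ValueError):
    """Sequence could not be anchored to the tRNAleu-cox2 region."""


class AmbiguousPForm(ValueError):
    """P-element alignment shows an uninterpretable deletion pattern."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ElementMap:
    """Located element spans (0-based, half-open) on the oriented sequence."""

    trnaleu_span: tuple[int, int]
    p_span: tuple[int, int] | None
    q_spans: list[tuple[int, int]]
    cox2_span: tuple[int, int]
    p_form: str
    dra1_sites: list[int]              # 0-based starts of TTTAAA
    strand: str = "+"                  # "-" if the input was reverse-complemented

    def validate(self) -> None:
        spans = [self.trnaleu_span]
        if self.p_span is not None:
            spans.append(self.p_span)
        spans.extend(self.q_spans)
        spans.append(self.cox2_span)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if not (a <= b <= c <= d):
                raise ValueError(f"element spans out of order: {spans}")
        if (self.p_form == "absent") != (self.p_span is None):
            raise ValueError("p_form/p_span inconsistency")
        if not 0 <= len(self.q_spans) <= grammar.MAX_Q_COPIES:
            raise ValueError("implausible Q copy count")


@dataclass
class TypingResult:
    """Per-colony call."""

    sample_id: str
    element_map: ElementMap
    lineage: str
    sublineage: str
    pattern: str
    haplotype: str
    novel: bool
    closest_reference: str
    edits_vs_closest: tuple[Edit, ...]
    site: str = ""
    region: str = ""
    notes: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Element location
# ---------------------------------------------------------------------------

def _infix_match(template: str, seq: str, min_identity: float
                 ) -> tuple[int, int] | None:
    """Best semi-global match of template within seq, or None below the
    identity threshold.  Returns a 0-based half-open span."""
    max_ed = int(round(len(template) * (1.0 - min_identity)))
    res = edlib.align(template, seq, mode="HW", task="locations", k=max_ed)
    ed = res["editDistance"]
    if ed < 0 or ed > max_ed or not res["locations"]:
        return None
    start, end = res["locations"][0]
    if start is None or end is None or end < 0:  # degenerate target
        return None
    return start, end + 1


def orient_sequence(seq: str) -> tuple[str, str]:
    """Return (sequence in E2->H2 orientation, strand flag).

    Orientation is decided by which strand aligns the tRNAleu and cox2
    anchors better (summed semi-global edit distance).
    """
    rc = reverse_complement(seq)
    fwd = rev = 0
    for template in (grammar.TEMPLATES["trnaleu"], grammar.TEMPLATES["cox2"]):
        fwd += edlib.align(template, seq, mode="HW")["editDistance"]
        rev += edlib.align(template, rc, mode="HW")["editDistance"]
    if fwd <= rev:
        return seq, "+"
    return rc, "-"


def locate_elements(sequence: str) -> ElementMap:
    """Locate tRNAleu, P, tandem Q copies and cox2 within one amplicon."""
    if len(sequence) < 150:
        raise UnrecognizedAmplicon(
            f"sequence too short to be a tRNAleu-cox2 amplicon ({len(sequence)} bp)")
    seq, strand = orient_sequence(sequence)

    trna_span = _infix_match(grammar.TEMPLATES["trnaleu"], seq, ANCHOR_MIN_IDENTITY)
    cox2_span = _infix_match(grammar.TEMPLATES["cox2"], seq, ANCHOR_MIN_IDENTITY)
    if trna_span is None and cox2_span is None:
        raise UnrecognizedAmplicon("neither the tRNAleu nor the cox2 anchor "
                                   "matched at >=80% identity")
    if trna_span is None or cox2_span is None:
        missing = "tRNAleu" if trna_span is None else "cox2"
        raise UnrecognizedAmplicon(f"{missing} anchor not found at >=80% identity")

    # iteratively peel tandem Q copies out of the inter-anchor interval
    inter_start, inter_end = trna_span[1], cox2_span[0]
    if inter_end < inter_start:
        raise UnrecognizedAmplicon("anchors overlap: cox2 precedes tRNAleu")
    middle = list(seq[inter_start:inter_end])
    q_template = grammar.TEMPLATES["q"]
    q_spans: list[tuple[int, int]] = []
    for _ in range(grammar.MAX_Q_COPIES):
        hit = _infix_match(q_template, "".join(middle), Q_MIN_IDENTITY)
        if hit is None:
            break
        s, e = hit
        q_spans.append((inter_start + s, inter_start + e))
        middle[s:e] = "X" * (e - s)
    q_spans.sort()
    for (_, a), (b, _) in zip(q_spans, q_spans[1:]):
        if b < a:
            raise UnrecognizedAmplicon("overlapping Q repeat matches")

    p_end = q_spans[0][0] if q_spans else cox2_span[0]
    p_span = (trna_span[1], p_end) if p_end - trna_span[1] >= MIN_P_REGION else None

    sites = []
    pos = seq.find(grammar.DRAI_MOTIF)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(grammar.DRAI_MOTIF, pos + 1)

    emap = ElementMap(trnaleu_span=trna_span, p_span=p_span, q_spans=q_spans,
                      cox2_span=cox2_span, p_form="absent", dra1_sites=sites,
                      strand=strand)
    emap.p_form = classify_p_form(emap, seq)
    emap.validate()
    return emap


# ---------------------------------------------------------------------------
# P form, lineage, sub-lineage, pattern
# ---------------------------------------------------------------------------

def classify_p_form(element_map: ElementMap, sequence: str) -> str:
    """Decide the P-element form from gap placement in the P0 alignment.

    Forms: no large gap -> P0; internal ~13 bp gap -> P; 3'-terminal ~15 bp
    gap -> P1; 5'-terminal ~18 bp gap -> P2 (gap lengths within +-2 bp).
    """
    if element_map.p_span is None:
        return "absent"
    seq, _ = orient_sequence(sequence)
    p_seq = seq[element_map.p_span[0]:element_map.p_span[1]]
    template = grammar.TEMPLATES["p0"]
    res = edlib.align(p_seq, template, mode="NW", task="path")
    runs: list[tuple[int, int]] = []  # deletion runs: (template start, length)
    tpos = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "D":        # bases of the P0 template absent from the query
            runs.append((tpos, n))
            tpos += n
        elif op in "=X":
            tpos += n
        # "I": extra query bases; no template advance
    # A deletion block may be split by coincidental 1-2 bp matches at its
    # flanks; merge deletion runs separated by <=3 aligned template bases.
    # Each merged entry is (span start, span end, total deleted bases).
    merged: list[tuple[int, int, int]] = []
    for start, length in runs:
        if merged and start - merged[-1][1] <= 3:
            ps, _pe, pdel = merged.pop()
            merged.append((ps, start + length, pdel + length))
        else:
            merged.append((start, start + length, length))
    gaps = [g for g in merged if g[2] >= LARGE_GAP_MIN]
    if not gaps:
        return "P0"
    if len(gaps) > 1:
        raise AmbiguousPForm(
            f"two or more large deletions in the P element: {gaps}")
    start, end, length = gaps[0]
    if start <= 3:                     # 5'-terminal
        expected, form = 18, "P2"
    elif end >= len(template) - 3:     # 3'-terminal
        expected, form = 15, "P1"
    else:
        expected, form = 13, "P"
    if abs(length - expected) > GAP_LEN_TOL:
        raise AmbiguousPForm(
            f"large deletion of {length} bp at template position {start} does "
            f"not fit any known P form")
    return form


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def assign_lineage(p_form: str) -> str:
    """Maternal lineage from the P-element form (total function)."""
    return {"P0": "A", "P1": "A", "P": "M", "P2": "Y", "absent": "C"}[p_form]


def assign_sublineage(p_form: str, dra1_sites: list[int],
                      element_map: ElementMap) -> str:
    """African sub-lineage from P form and DraI site placement.

    Windows: the last 10 bp of the tRNAleu span (with 6 bp of 3' slack), the
    first 15 bp of the first Q copy, and the central third of the first Q
    copy.  AIII is called on the P1 form alone.  With no Q copy present, a
    tRNAleu-only DraI configuration is called AI (the configuration of the
    only known Q-less haplotype, A65); without that site the sub-lineage is
    indeterminate and reported as ``none``.
    """
    if assign_lineage(p_form) != "A":
        return "none"
    if p_form == "P1":
        return "AIII"

    t_lo = element_map.trnaleu_span[1] - 10
    t_hi = element_map.trnaleu_span[1] + 6
    has_trna = any(t_lo <= s < t_hi for s in dra1_sites)
    if not element_map.q_spans:
        return "AI" if has_trna else "none"
    q_lo, q_hi = element_map.q_spans[0]
    q_len = q_hi - q_lo
    has_q5 = any(q_lo <= s < q_lo + 15 for s in dra1_sites)
    has_mid = any(q_lo + q_len // 3 <= s < q_lo + 2 * q_len // 3
                  for s in dra1_sites)
    if has_trna and has_q5 and has_mid:
        return "Z"
    if has_trna and has_q5:
        return "AI"
    if has_trna:
        return "AII"
    return "none"


def length_pattern(element_map: ElementMap) -> str:
    """Element architecture string, e.g. ``P0QQ``, ``Q``, ``P0``."""
    token = "" if element_map.p_form == "absent" else element_map.p_form
    return token + "Q" * len(element_map.q_spans)


# ---------------------------------------------------------------------------
# Haplotype calling
# ---------------------------------------------------------------------------

def _observed_edits(seq: str, family: str, catalog: HaplotypeCatalog
                    ) -> tuple[Edit, ...]:
    """Differences between a sequence and a family base, as master-alignment
    edits.  1 bp insertions are assigned to the designated insertion-slot
    columns of the master alignment when one exists at that junction."""
    family_row = catalog.family_base_row(family)
    base_seq = grammar.degap(family_row)
    base_cols = grammar.base_columns_of_row(family_row)
    res = edlib.align(seq, base_seq, mode="NW", task="path")
    edits: list[Edit] = []
    qpos = tpos = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            qpos += n
            tpos += n
        elif op == "X":
            for k in range(n):
                edits.append(Edit(base_cols[tpos + k], base_seq[tpos + k],
                                  seq[qpos + k]))
            qpos += n
            tpos += n
        elif op == "D":
            for k in range(n):
                edits.append(Edit(base_cols[tpos + k], base_seq[tpos + k], "-"))
            tpos += n
        elif op == "I":
            left = base_cols[tpos - 1] if tpos > 0 else 0
            right = base_cols[tpos] if tpos < len(base_cols) else (
                grammar.ALIGNMENT_LENGTH + 1)
            slots = sorted(c for c in grammar.INSERTION_COLUMNS
                           if left < c < right)
            for k in range(n):
                col = slots[k] if k < len(slots) else right
                edits.append(Edit(col, "-", seq[qpos + k]))
            qpos += n
    return tuple(sorted(edits))


def _next_variant_name(family: str, catalog: HaplotypeCatalog) -> str:
    """Coin a new variant name: family base + first unused letter suffix."""
    used = set()
    for rec in catalog:
        if rec.family == family and rec.name.startswith(family):
            suffix = rec.name[len(family):]
            if len(suffix) == 1 and suffix in string.ascii_lowercase:
                used.add(suffix)
    for letter in string.ascii_lowercase:
        if letter not in used and (family + letter) not in catalog:
            return family + letter
    raise RuntimeError(f"letter suffixes exhausted for family {family}")


def call_haplotype(sequence: str, element_map: ElementMap,
                   catalog: HaplotypeCatalog, sample_id: str = "") -> TypingResult:
    """Name a typed amplicon against the catalog.

    The sequence is compared, in master-alignment edit space, with every
    catalog member sharing its length pattern.  An exact edit-list match
    returns that name; otherwise the closest reference (minimum number of
    differing edits; ties broken by catalog order) anchors a newly coined
    name, family base + next unused letter suffix.
    """
    seq, _ = orient_sequence(sequence)
    lineage = assign_lineage(element_map.p_form)
    sublineage = assign_sublineage(element_map.p_form, element_map.dra1_sites,
                                   element_map)
    pattern = length_pattern(element_map)
    notes: list[str] = []
    if lineage == "A" and sublineage == "none":
        notes.append("indeterminate sub-lineage")

    candidates = catalog.members_with_pattern(pattern)
    if not candidates:
        return TypingResult(
            sample_id=sample_id, element_map=element_map, lineage=lineage,
            sublineage=sublineage, pattern=pattern, haplotype="X1", novel=True,
            closest_reference="", edits_vs_closest=(),
            notes=tuple(notes + ["no catalog member shares this pattern; "
                                 "flagged for curation"]))

    by_family: dict[str, tuple[Edit, ...]] = {}
    best: tuple[int, int, HaplotypeRecord] | None = None
    best_obs: tuple[Edit, ...] = ()
    for idx, rec in enumerate(candidates):
        if rec.family not in by_family:
            by_family[rec.family] = _observed_edits(seq, rec.family, catalog)
        obs = by_family[rec.family]
        dist = len(set(obs) ^ set(rec.edits))
        if best is None or dist < best[0]:
            best = (dist, idx, rec)
            best_obs = obs
    assert best is not None
    dist, _, closest = best

    if dist == 0:
        return TypingResult(
            sample_id=sample_id, element_map=element_map, lineage=lineage,
            sublineage=sublineage, pattern=pattern, haplotype=closest.name,
            novel=False, closest_reference=closest.name, edits_vs_closest=(),
            notes=tuple(notes))

    diff = tuple(sorted(set(best_obs) ^ set(closest.edits)))
    return TypingResult(
        sample_id=sample_id, element_map=element_map, lineage=lineage,
        sublineage=sublineage, pattern=pattern,
        haplotype=_next_variant_name(closest.family, catalog), novel=True,
        closest_reference=closest.name, edits_vs_closest=diff,
        notes=tuple(notes))


def type_sequence(sequence: str, catalog: HaplotypeCatalog,
                  sample_id: str = "") -> TypingResult:
    """Locate elements and call the haplotype for one amplicon."""
    emap = locate_elements(sequence)
    return call_haplotype(sequence, emap, catalog, sample_id=sample_id)


def type_sequences(records, catalog: HaplotypeCatalog,
                   sample_sheet=None) -> list[TypingResult]:
    """Type a collection of (id, sequence) records; attach site/region from a
    sample sheet DataFrame when given."""
    meta = {}
    if sample_sheet is not None:
        meta = {row.sample_id: (row.site, row.region)
                for row in sample_sheet.itertuples(index=False)}
    results = []
    for rid, seq in records:
        res = type_sequence(seq, catalog, sample_id=rid)
        if rid in meta:
            res.site, res.region = meta[rid]
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# In-silico DraI digestion
# ---------------------------------------------------------------------------

def insilico_dra1_digest(sequence: str) -> list[int]:
    """Fragment lengths of a DraI digest (TTT^AAA), 5' to 3'.

    Fragment lengths always sum to the input length; the number of fragments
    is the number of TTTAAA occurrences plus one.
    """
    if not sequence:
        raise ValueError("empty sequence")
    cuts = []
    pos = sequence.find(grammar.DRAI_MOTIF)
    while pos != -1:
        cuts.append(pos + 3)
        pos = sequence.find(grammar.DRAI_MOTIF, pos + 1)
    bounds = [0] + cuts + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:])]
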