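"""Synthetic element grammar for the honey bee tRNAleu-cox2 intergenic region.

The real tRNAleu-cox2 amplicon is a mosaic of a tRNAleu fragment, a P element
occurring in four forms (P0: full length; P: 13 bp deletion in the middle;
P1: 15 bp deletion at the 3' end; P2: 18 bp deletion at the 5' end; or absent
in lineage C), one to five tandem copies of a ~196 bp Q element, and the start
of the cox2 gene.  African sub-lineages are diagnosed by where DraI (TTTAAA)
restriction sites sit relative to the tRNAleu and the first Q copy.

Because no reference alignment of the region is distributed with this package,
the grammar below defines its *own* deterministic synthetic templates for each
element and a fixed master-alignment column layout.  All haplotype definitions,
variant edit lists, classifier templates and simulated amplicons share this
single coordinate system, so positions quoted in the reference catalog are
1-based columns of this master alignment.

Layout (1-based, inclusive master-alignment columns)::

    tRNAleu   1-40     40 bases
    P         41-109   68 bases of the full-length P0 (column 100 is an
                       insertion slot that is a gap in every family base)
    Q1        110-307  196 bases (columns 139 and 298 are insertion slots)
    Q2        308-504  196 bases (column 337 is an insertion slot)
    cox2      505-818  314 bases

The four insertion-slot columns host the 1 bp insertions that define named
variants; they are gaps in all family base sequences.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Master-alignment layout
# ---------------------------------------------------------------------------

ALIGNMENT_LENGTH = 818

TRNA_COLS = (1, 40)
P_COLS = (41, 109)
Q1_COLS = (110, 307)
Q2_COLS = (308, 504)
COX2_COLS = (505, 818)

#: Columns that are gaps in every family base and carry variant insertions.
INSERTION_COLUMNS = frozenset({100, 139, 298, 337})

TRNA_LEN = 40
P0_LEN = 68
Q_LEN = 196
COX2_LEN = 314

#: P-form deletion blocks, as 1-based base indices within the 68 bp P0.
P_FORM_DELETIONS = {
    "P": (28, 40),   # 13 bp removed from the middle       -> lineage M
    "P1": (54, 68),  # 15 bp removed from the 3' end       -> sub-lineage AIII
    "P2": (1, 18),   # 18 bp removed from the 5' end       -> lineage Y
}

P_FORMS = ("P0", "P", "P1", "P2", "absent")
MAX_Q_COPIES = 5

DRAI_MOTIF = "TTTAAA"

#: DraI site placements, as (element, 1-based offset of the site start within
#: that element's bases).  The tRNAleu site occupies the last six bases of the
#: tRNAleu fragment; the Q sites sit at the 5' end and in the middle third of
#: the first Q copy.
DRAI_TRNA_OFFSET = 35       # tRNA bases 35-40
DRAI_Q5_OFFSET = 1          # Q bases 1-6
DRAI_QMID_OFFSET = 95       # Q bases 95-100

#: Which DraI sites each African sub-lineage template carries.
#: AIII shares the AI placement; it is distinguished by the P1 form instead.
SUBLINEAGE_DRAI = {
    "AI": ("trna", "q5"),
    "AII": ("trna",),
    "AIII": ("trna", "q5"),
    "Z": ("trna", "q5", "qmid"),
    "none": (),
}

SUBLINEAGES = ("AI", "AII", "AIII", "Z", "none")

_TEMPLATE_SEED = 20210714  # fixed: the templates are reference data, not RNG


# ---------------------------------------------------------------------------
# Canonical element templates
# ---------------------------------------------------------------------------

def _scrub_motif(seq: list[str], protected: set[int]) -> None:
    """Destroy every DraI motif occurrence in-place by switching one base to G
    (the motif contains no G).  ``protected`` holds 0-based indices that must
    not be touched."""
    i = 0
    while i <= len(seq) - 6:
        if "".join(seq[i:i + 6]) == DRAI_MOTIF:
            for j in range(i, i + 6):
                if j not in protected:
                    seq[j] = "G"
                    break
            else:  # pragma: no cover - layout guarantees a free base
                raise AssertionError("cannot scrub DraI motif: all bases forced")
        i += 1


def _build_templates() -> dict[str, str]:
    rng = np.random.default_rng(_TEMPLATE_SEED)
    bases = np.array(list("ACGT"))

    def rand(n: int) -> list[str]:
        return list(rng.choice(bases, size=n))

    trna = rand(TRNA_LEN)
    p0 = rand(P0_LEN)
    q = rand(Q_LEN)
    cox2 = rand(COX2_LEN)

    # Bases pinned so the published variant edit lists are expressible and so
    # that 1 bp indels sit between unlike neighbours (keeps pairwise alignments
    # of variants against their family base unambiguous).
    forced_p0 = {44: "A", 46: "C", 59: "G", 60: "A"}
    forced_q = {28: "G", 29: "C", 30: "G", 38: "T", 141: "A", 142: "T",
                143: "G", 176: "T", 187: "G", 188: "G"}
    forced_cox2 = {142: "C", 235: "A", 291: "A"}
    for pos, b in forced_p0.items():
        p0[pos - 1] = b
    for pos, b in forced_q.items():
        q[pos - 1] = b
    for pos, b in forced_cox2.items():
        cox2[pos - 1] = b

    _scrub_motif(p0, {p - 1 for p in forced_p0})
    _scrub_motif(q, {p - 1 for p in forced_q})
    _scrub_motif(cox2, {p - 1 for p in forced_cox2})
    _scrub_motif(trna, set())

    # No DraI motif may arise across any element junction realisable by the
    # grammar (every P form, any Q copy number, element omissions).
    lefts = {
        "trna": trna[-5:],
        "p0_end": p0[-5:],
        "p1_end": p0[48:53],       # P1 ends at P0 base 53
        "p_mid": p0[22:27],        # P form: base 27 abuts base 41
        "q_end": q[-5:],
    }
    rights = {
        "p0_start": p0[:5],
        "p2_start": p0[18:23],     # P2 starts at P0 base 19
        "p_mid": p0[40:45],
        "q_start": q[:5],
        "cox2_start": cox2[:5],
    }
    element_of = {"trna": trna, "p0_end": p0, "p1_end": p0, "p_mid": p0,
                  "q_end": q}
    for _ in range(20):
        dirty = False
        for lname, left in lefts.items():
            for right in rights.values():
                joint = "".join(left) + "".join(right)
                if DRAI_MOTIF in joint:
                    elem = element_of[lname]
                    # mutate the last unforced base of the left flank
                    idx = len(elem) - 1 if lname != "p1_end" else 52
                    if lname == "p_mid":
                        idx = 26
                    elem[idx] = "G"
                    dirty = True
        if not dirty:
            break
        lefts = {
            "trna": trna[-5:], "p0_end": p0[-5:], "p1_end": p0[48:53],
            "p_mid": p0[22:27], "q_end": q[-5:],
        }

    return {
        "trnaleu": "".join(trna),
        "p0": "".join(p0),
        "q": "".join(q),
        "cox2": "".join(cox2),
    }


TEMPLATES = _build_templates()


# ---------------------------------------------------------------------------
# Column bookkeeping
# ---------------------------------------------------------------------------

def _region_base_columns(lo: int, hi: int) -> list[int]:
    return [c for c in range(lo, hi + 1) if c not in INSERTION_COLUMNS]


P_BASE_COLUMNS = _region_base_columns(*P_COLS)        # 68 columns
Q1_BASE_COLUMNS = _region_base_columns(*Q1_COLS)      # 196 columns
Q2_BASE_COLUMNS = _region_base_columns(*Q2_COLS)      # 196 columns
TRNA_BASE_COLUMNS = list(range(TRNA_COLS[0], TRNA_COLS[1] + 1))
COX2_BASE_COLUMNS = list(range(COX2_COLS[0], COX2_COLS[1] + 1))

assert len(P_BASE_COLUMNS) == P0_LEN
assert len(Q1_BASE_COLUMNS) == len(Q2_BASE_COLUMNS) == Q_LEN


def column_region(col: int) -> str:
    """Provenance of a master-alignment column."""
    if TRNA_COLS[0] <= col <= TRNA_COLS[1]:
        return "trnaleu"
    if P_COLS[0] <= col <= P_COLS[1]:
        return "P"
    if Q1_COLS[0] <= col <= Q1_COLS[1]:
        return "Q1"
    if Q2_COLS[0] <= col <= Q2_COLS[1]:
        return "Q2"
    if COX2_COLS[0] <= col <= COX2_COLS[1]:
        return "cox2"
    raise ValueError(f"column {col} outside master alignment")


def p_form_deleted_columns(p_form: str) -> set[int]:
    """Master columns blanked by a P-form large deletion."""
    if p_form == "P0":
        return set()
    if p_form == "absent":
        return set(P_BASE_COLUMNS)
    lo, hi = P_FORM_DELETIONS[p_form]
    return {P_BASE_COLUMNS[i - 1] for i in range(lo, hi + 1)}


#: DraI window columns (used both for planting and to keep per-column
#: character coding from double-counting the restriction-site differences).
DRAI_WINDOW_COLUMNS = {
    "trna": tuple(TRNA_BASE_COLUMNS[DRAI_TRNA_OFFSET - 1:DRAI_TRNA_OFFSET + 5]),
    "q5": tuple(Q1_BASE_COLUMNS[DRAI_Q5_OFFSET - 1:DRAI_Q5_OFFSET + 5]),
    "qmid": tuple(Q1_BASE_COLUMNS[DRAI_QMID_OFFSET - 1:DRAI_QMID_OFFSET + 5]),
}


# ---------------------------------------------------------------------------
# Aligned-row construction
# ---------------------------------------------------------------------------

def aligned_row(p_form: str, n_q: int, sublineage: str,
                family_subs: dict[int, str] | None = None) -> str:
    """Build an 818-column aligned sequence for one architecture.

    ``n_q`` may be 0, 1 or 2 here (the master alignment carries two Q slots;
    amplicons with more tandem copies are handled downstream by duplicating
    the Q unit in sequence space).  ``family_subs`` maps master columns to
    replacement bases and encodes the fixed differences between haplotype
    family bases (e.g. the A4 family state at column 99).
    """
    if p_form not in P_FORMS:
        raise ValueError(f"unknown P form {p_form!r}")
    if not 0 <= n_q <= 2:
        raise ValueError("aligned_row supports 0-2 Q copies")
    if sublineage not in SUBLINEAGES:
        raise ValueError(f"unknown sub-lineage template {sublineage!r}")
    if sublineage != "none" and p_form not in ("P0", "P1"):
        raise ValueError("African sub-lineage templates require the P0/P1 form")

    row = ["-"] * ALIGNMENT_LENGTH

    def put(columns: list[int], seq: str) -> None:
        for col, base in zip(columns, seq):
            row[col - 1] = base

    put(TRNA_BASE_COLUMNS, TEMPLATES["trnaleu"])
    if p_form != "absent":
        put(P_BASE_COLUMNS, TEMPLATES["p0"])
        for col in p_form_deleted_columns(p_form):
            row[col - 1] = "-"
    if n_q >= 1:
        put(Q1_BASE_COLUMNS, TEMPLATES["q"])
    if n_q >= 2:
        put(Q2_BASE_COLUMNS, TEMPLATES["q"])
    put(COX2_BASE_COLUMNS, TEMPLATES["cox2"])

    for site in SUBLINEAGE_DRAI[sublineage]:
        cols = DRAI_WINDOW_COLUMNS[site]
        if site in ("q5", "qmid") and n_q == 0:
            continue  # no Q copy to host the site (A65-like architecture)
        put(list(cols), DRAI_MOTIF)

    if family_subs:
        for col, base in family_subs.items():
            if row[col - 1] == "-":
                raise ValueError(f"family substitution at gap column {col}")
            row[col - 1] = base
    return "".join(row)


def apply_edits(row: str, edits) -> str:
    """Apply an edit list (sequence of Edit-like tuples with 1-based master
    columns) to an aligned row, checking reference states."""
    chars = list(row)
    for e in edits:
        col, ref, alt = e.column, e.ref, e.alt
        have = chars[col - 1]
        if have != ref:
            raise ValueError(
                f"edit at column {col}: expected {ref!r}, alignment has {have!r}")
        chars[col - 1] = alt
    return "".join(chars)


def degap(row: str) -> str:
    return row.replace("-", "")


def base_columns_of_row(row: str) -> list[int]:
    """1-based master columns occupied by bases in an aligned row."""
    return [i + 1 for i, ch in enumerate(row) if ch != "-"]


# ---------------------------------------------------------------------------
# Synthetic outgroup (Apis cerana analogue)
# ---------------------------------------------------------------------------

def outgroup_row() -> str:
    """Aligned outgroup sequence: carries the tRNAleu, a diverged full-length
    P element and a diverged cox2 fragment but no Q element, mirroring the
    architecture of Apis cerana."""
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    row = list(aligned_row("P0", 0, "none"))
    # sprinkle fixed divergence outside pinned/editable columns
    editable = {84, 86, 99, 148, 160, 170, 180, 190, 252, 286, 336,
                646, 660, 670, 739, 795}
    p_cols = [c for c in P_BASE_COLUMNS if c not in editable]
    cox_cols = [c for c in COX2_BASE_COLUMNS if c not in editable]
    trna_cols = [c for c in TRNA_BASE_COLUMNS
                 if c not in DRAI_WINDOW_COLUMNS["trna"]]
    for cols, k in ((p_cols, 10), (cox_cols, 16), (trna_cols, 4)):
        for col in rng.choice(cols, size=k, replace=False):
            old = row[col - 1]
            alts = [b for b in "ACGT" if b != old]
            row[col - 1] = alts[int(rng.integers(len(alts)))]
    seq = degap("".join(row))
    assert DRAI_MOTIF not in seq, "outgroup divergence created a DraI site"
    return "".join(row)
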