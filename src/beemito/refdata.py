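"""Reference haplotype catalog and external-format I/O.

The catalog encodes 26 named haplotypes of the tRNAleu-cox2 intergenic region
found in (or relevant to) Peruvian honey bee populations: 16 of lineage A
(13 sub-lineage AI, 3 sub-lineage AIII), 6 of lineage C, 2 of lineage M, plus
the A4 and M7 family base sequences used as alignment anchors.  Each named
variant is stored as an edit list (substitutions and 1 bp indels, 1-based
master-alignment columns) against its family base; the family bases are built
from the synthetic element grammar in :mod:`beemito.grammar`.

External formats handled here: FASTA (strict ACGTN alphabet), the sample
sheet TSV (``sample_id<TAB>site<TAB>region``), the typing-table TSV, and the
two shipped package-data files (catalog TSV + aligned FASTA).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO

from . import grammar

LINEAGES = ("A", "M", "C", "Y")
SUBLINEAGES = ("AI", "AII", "AIII", "Z", "none")

_VALID_BASES = set("ACGTN")


class Edit(NamedTuple):
    """One difference vs a family base, in master-alignment coordinates."""

    column: int   # 1-based master-alignment column
    ref: str      # base in the family base sequence, or "-" for insertions
    alt: str      # base in the variant, or "-" for deletions

    @property
    def kind(self) -> str:
        if self.ref == "-":
            return "insertion"
        if self.alt == "-":
            return "deletion"
        return "substitution"

    def encode(self) -> str:
        return f"{self.column}:{self.ref}>{self.alt}"

    @classmethod
    def decode(cls, text: str) -> "Edit":
        pos, _, change = text.partition(":")
        ref, _, alt = change.partition(">")
        return cls(int(pos), ref, alt)


@dataclass(frozen=True)
class HaplotypeRecord:
    name: str
    lineage: str
    sublineage: str
    pattern: str          # e.g. "P0QQ", "Q", "P0"
    family: str           # family base name this record's edits refer to
    edits: tuple[Edit, ...]
    novel: bool           # first reported in the Peruvian survey
    observed: bool        # seen in the survey (family anchors A4/M7 were not)

    def validate(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"{self.name}: bad lineage {self.lineage}")
        if self.sublineage not in SUBLINEAGES:
            raise ValueError(f"{self.name}: bad sub-lineage {self.sublineage}")
        starts = self.pattern[:2]
        if self.lineage == "A" and not (starts in ("P0", "P1")):
            raise ValueError(f"{self.name}: lineage A needs a P0/P1 pattern")
        if self.lineage == "M" and not (
                self.pattern.startswith("P") and starts not in ("P0", "P1", "P2")):
            raise ValueError(f"{self.name}: lineage M needs the P form")
        if self.lineage == "C" and "P" in self.pattern:
            raise ValueError(f"{self.name}: lineage C must lack the P element")
        if self.lineage != "A" and self.sublineage != "none":
            raise ValueError(f"{self.name}: sub-lineage set for non-A lineage")


class CatalogIntegrityError(RuntimeError):
    """Shipped catalog data failed its consistency checks."""


@dataclass
class HaplotypeCatalog:
    records: list[HaplotypeRecord]
    master_alignment: dict[str, str]       # name -> aligned row (818 cols)
    outgroup_name: str
    outgroup_row: str

    _by_name: dict[str, HaplotypeRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {r.name: r for r in self.records}
        if len(self._by_name) != len(self.records):
            raise CatalogIntegrityError("duplicate haplotype names in catalog")

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> HaplotypeRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown haplotype {name!r}") from None

    def aligned(self, name: str) -> str:
        return self.master_alignment[name]

    def sequence(self, name: str) -> str:
        """Ungapped amplicon sequence of a catalog haplotype."""
        return grammar.degap(self.master_alignment[name])

    def members_with_pattern(self, pattern: str) -> list[HaplotypeRecord]:
        return [r for r in self.records if r.pattern == pattern]

    def family_base_row(self, family: str) -> str:
        return self.master_alignment[family]

    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def validate(self) -> None:
        """Check every catalog invariant; raise CatalogIntegrityError."""
        try:
            for rec in self.records:
                rec.validate()
                row = self.master_alignment[rec.name]
                if len(row) != grammar.ALIGNMENT_LENGTH:
                    raise ValueError(f"{rec.name}: bad alignment length")
                base = self.master_alignment[rec.family]
                if grammar.apply_edits(base, rec.edits) != row:
                    raise ValueError(
                        f"{rec.name}: edits do not reproduce aligned sequence")
            if len(self.outgroup_row) != grammar.ALIGNMENT_LENGTH:
                raise ValueError("outgroup: bad alignment length")
        except (ValueError, KeyError) as exc:
            raise CatalogIntegrityError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Catalog definition
# ---------------------------------------------------------------------------

#: family base -> (pattern, lineage, sublineage, fixed substitutions vs the
#: canonical templates)
_FAMILY_DEFS = {
    "A1":  ("P0Q",  "A", "AI",   {}),
    "A4":  ("P0QQ", "A", "AI",   {99: "A"}),
    "A30": ("P1QQ", "A", "AIII", {}),
    "A65": ("P0",   "A", "AI",   {}),
    "C2":  ("Q",    "C", "none", {}),
    "M7":  ("PQQ",  "M", "none", {}),
}

_OUTGROUP_NAME = "Acerana_syn"


def _c_edit(base_row: str, col: int) -> Edit:
    """Invented single-base substitution for a lineage-C variant: the C-family
    variant structure (which variant diverged from which) follows the survey's
    network, but the exact columns are this package's own choice."""
    ref = base_row[col - 1]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    return Edit(col, ref, alt)


def build_catalog() -> HaplotypeCatalog:
    """Construct the reference catalog from the element grammar.

    This is the generator behind the shipped package-data files; loading via
    :func:`load_reference_catalog` is the normal entry point.
    """
    rows: dict[str, str] = {}
    for fam, (pattern, _lin, sub, subs) in _FAMILY_DEFS.items():
        p_form = pattern[:2] if pattern[:2] in ("P0", "P1") else (
            "P" if pattern.startswith("P") else "absent")
        n_q = pattern.count("Q")
        rows[fam] = grammar.aligned_row(p_form, n_q, sub, subs)

    a1, c2 = rows["A1"], rows["C2"]
    sub646 = Edit(646, "C", "T")

    variant_edits: dict[str, tuple[str, tuple[Edit, ...]]] = {
        # lineage A, sub-lineage AI --------------------------------------
        "A1e": ("A1", (_c_edit(a1, 160),)),
        "A1t": ("A1", (Edit(99, "G", "A"), Edit(139, "-", "A"), sub646)),
        "A1u": ("A1", (Edit(99, "G", "A"), Edit(286, "T", "C"))),
        "A1w": ("A1", (Edit(100, "-", "G"), sub646)),
        "A4p": ("A4", (Edit(99, "A", "G"), Edit(100, "-", "G"), sub646)),
        "A4q": ("A4", (Edit(99, "A", "G"), Edit(100, "-", "G"),
                       Edit(298, "-", "A"), sub646)),
        "A4s": ("A4", (Edit(337, "-", "A"), sub646)),
        "A4t": ("A4", (Edit(252, "T", "-"), Edit(337, "-", "A"), sub646)),
        "A4u": ("A4", (Edit(252, "T", "-"), sub646)),
        "A4v": ("A4", (Edit(252, "T", "-"), Edit(337, "-", "A"), sub646,
                       Edit(739, "A", "T"))),
        "A4w": ("A4", (Edit(252, "T", "-"), Edit(337, "-", "A"), sub646,
                       Edit(795, "A", "T"))),
        # lineage A, sub-lineage AIII ------------------------------------
        "A30d": ("A30", (Edit(336, "C", "-"),)),
        "A30e": ("A30", (Edit(86, "C", "A"),)),
        # lineage C -------------------------------------------------------
        "C2c": ("C2", (_c_edit(c2, 170),)),
        "C2j": ("C2", (_c_edit(c2, 180),)),
        "C3":  ("C2", (_c_edit(c2, 190),)),
        "C1":  ("C2", (_c_edit(c2, 170), _c_edit(c2, 660))),
        "C2l": ("C2", (_c_edit(c2, 170), _c_edit(c2, 670))),
        # lineage M -------------------------------------------------------
        "M7b": ("M7", (Edit(84, "A", "G"),)),
        "M7c": ("M7", (Edit(84, "A", "G"), Edit(148, "T", "C"))),
    }

    novel = {"A1t", "A1u", "A1w", "A4p", "A4q", "A4s", "A4t", "A4u", "A4v",
             "A4w", "A30d", "A30e", "A65", "M7b", "M7c"}
    unobserved = {"A4", "M7"}

    order = ["A1", "A1e", "A1t", "A1u", "A1w",
             "A4", "A4p", "A4q", "A4s", "A4t", "A4u", "A4v", "A4w",
             "A30", "A30d", "A30e", "A65",
             "C1", "C2", "C2c", "C2j", "C2l", "C3",
             "M7", "M7b", "M7c"]

    records: list[HaplotypeRecord] = []
    alignment: dict[str, str] = {}
    for name in order:
        if name in _FAMILY_DEFS:
            fam, edits = name, ()
        else:
            fam, edits = variant_edits[name]
        pattern, lin, sub, _ = _FAMILY_DEFS[fam]
        rec = HaplotypeRecord(
            name=name, lineage=lin, sublineage=sub, pattern=pattern,
            family=fam, edits=tuple(edits), novel=name in novel,
            observed=name not in unobserved)
        records.append(rec)
        alignment[name] = grammar.apply_edits(rows[fam], rec.edits)

    cat = HaplotypeCatalog(records=records, master_alignment=alignment,
                           outgroup_name=_OUTGROUP_NAME,
                           outgroup_row=grammar.outgroup_row())
    cat.validate()
    return cat


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _find_header_line(path: Path, record_id: str) -> int | None:
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(">") and line[1:].split()[:1] == [record_id]:
                    return lineno
    except OSError:
        pass
    return None


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs.

    The alphabet is strict ACGTN: Sanger consensus amplicons are expected, so
    IUPAC ambiguity codes are rejected with an error naming the offending
    record and line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty FASTA file")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad or not seq:
            line = _find_header_line(path, rec.id)
            where = f" (line {line})" if line else ""
            what = f"invalid characters {sorted(bad)}" if bad else "empty sequence"
            raise ValueError(f"{path}: record {rec.id!r}{where}: {what}")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Sample sheet and typing table
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "site", "region"]
TYPING_TABLE_COLUMNS = ["sample_id", "site", "region", "lineage", "sublineage",
                        "pattern", "haplotype", "n_edits_vs_closest"]


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != SAMPLE_SHEET_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {SAMPLE_SHEET_COLUMNS}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    regions_per_site = df.groupby("site")["region"].nunique()
    if (regions_per_site > 1).any():
        site = regions_per_site[regions_per_site > 1].index[0]
        raise ValueError(f"{path}: site {site!r} maps to multiple regions")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SAMPLE_SHEET_COLUMNS)


def write_typing_table(results, path) -> None:
    """Write per-colony typing calls as TSV, one row per sample in input order."""
    rows = list(results)
    if not rows:
        raise ValueError("no typing results to write")
    df = pd.DataFrame(
        [{
            "sample_id": r.sample_id,
            "site": r.site,
            "region": r.region,
            "lineage": r.lineage,
            "sublineage": r.sublineage,
            "pattern": r.pattern,
            "haplotype": r.haplotype,
            "n_edits_vs_closest": len(r.edits_vs_closest),
        } for r in rows],
        columns=TYPING_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_typing_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str,
                                            "region": str})
    missing = set(TYPING_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: typing table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Package data
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return (resources.files("beemito") / "data" / name).read_text()


def load_reference_catalog() -> HaplotypeCatalog:
    """Load the shipped reference catalog (TSV of records + aligned FASTA)."""
    try:
        tsv = _data_text("catalog_records.tsv")
        fasta = _data_text("catalog_alignment.fasta")
    except (FileNotFoundError, OSError) as exc:
        raise CatalogIntegrityError(f"catalog package data missing: {exc}")

    alignment: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(fasta), "fasta"):
        alignment[rec.id] = str(rec.seq)

    df = pd.read_csv(io.StringIO(tsv), sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        edits = tuple(Edit.decode(e) for e in row.edits.split(";") if e)
        records.append(HaplotypeRecord(
            name=row.name, lineage=row.lineage, sublineage=row.sublineage,
            pattern=row.pattern, family=row.family, edits=edits,
            novel=row.novel == "1", observed=row.observed == "1"))

    outgroup_name = _OUTGROUP_NAME
    if outgroup_name not in alignment:
        raise CatalogIntegrityError("outgroup row missing from catalog alignment")
    cat = HaplotypeCatalog(
        records=records,
        master_alignment={n: s for n, s in alignment.items() if n != outgroup_name},
        outgroup_name=outgroup_name,
        outgroup_row=alignment[outgroup_name])
    cat.validate()
    return cat


def write_catalog_data(cat: HaplotypeCatalog, directory) -> None:
    """Write the catalog to the TSV + aligned-FASTA package-data pair."""
    directory = Path(directory)
    df = pd.DataFrame([{
        "name": r.name, "lineage": r.lineage, "sublineage": r.sublineage,
        "pattern": r.pattern, "family": r.family,
        "edits": ";".join(e.encode() for e in r.edits),
        "novel": int(r.novel), "observed": int(r.observed),
    } for r in cat.records])
    df.to_csv(directory / "catalog_records.tsv", sep="\t", index=False)
    recs = [(r.name, cat.master_alignment[r.name]) for r in cat.records]
    recs.append((cat.outgroup_name, cat.outgroup_row))
    with open(directory / "catalog_alignment.fasta", "w") as fh:
        for rid, seq in recs:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def load_site_diversity_reference() -> pd.DataFrame:
    """Published per-site diversity table for the 512-colony Peruvian survey
    (region, site, N, Na, Np, Ne, uh).  Used as an input for identity checks
    between N, Ne and the unbiased haplotype diversity."""
    return pd.read_csv(io.StringIO(_data_text("site_diversity_reference.tsv")),
                       sep="\t")


def load_default_composition() -> pd.DataFrame:
    """Default site-by-haplotype composition of the simulated survey
    (region, site, haplotype, count): a deterministic reconstruction matching
    the published totals (512 colonies; lineage counts 333 A / 173 C / 6 M;
    280 AI / 53 AIII; the printed per-haplotype and per-pattern counts; one
    private haplotype per site)."""
    df = pd.read_csv(io.StringIO(_data_text("default_composition.tsv")),
                     sep="\t", dtype={"count": int})
    return df
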