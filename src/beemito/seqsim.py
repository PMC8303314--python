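"""Synthetic amplicon generator for the tRNAleu-cox2 intergenic region.

Produces labeled amplicons from the element grammar: a chosen P form, 0-5
tandem Q copies, sub-lineage specific DraI placements and the catalog's named
variant edits, so the classifier and every downstream statistic can be tested
against known truth.  The default population configuration reproduces the
15-site, 512-colony Peruvian survey composition shipped as package data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import grammar
from .refdata import Edit, HaplotypeCatalog, load_default_composition

TRUTH_COLUMNS = ["sample_id", "haplotype", "lineage", "sublineage", "pattern"]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural description of one amplicon to synthesize."""

    p_form: str = "P0"                      # P0 | P | P1 | P2 | absent
    n_q: int = 1                            # 0-5 tandem Q copies
    sublineage_template: str = "none"       # AI | AII | AIII | Z | none
    variant_edits: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        if self.p_form not in grammar.P_FORMS:
            raise ValueError(f"unknown P form {self.p_form!r}")
        if not 0 <= self.n_q <= grammar.MAX_Q_COPIES:
            raise ValueError(f"n_q must be 0-{grammar.MAX_Q_COPIES}")
        if self.sublineage_template not in grammar.SUBLINEAGES:
            raise ValueError(
                f"unknown sub-lineage template {self.sublineage_template!r}")
        if self.sublineage_template != "none" and self.p_form not in ("P0", "P1"):
            raise ValueError("sub-lineage templates require the P0 or P1 form")


@dataclass
class PopulationConfig:
    """Sampling design for a simulated survey.

    ``composition`` maps (site, region) to either exact per-haplotype counts
    (deterministic mode, ints) or frequencies (multinomial mode, floats
    summing to 1 with ``n_colonies`` set).  The default configuration uses
    exact counts so published proportion arithmetic is reproduced exactly.
    """

    sites: list[tuple[str, str]]                       # (site, region)
    haplotype_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    haplotype_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    n_colonies: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self, catalog: HaplotypeCatalog) -> None:
        if not self.sites:
            raise ValueError("population config has no sites")
        names = {s for s, _ in self.sites}
        if len(names) != len(self.sites):
            raise ValueError("duplicate site names in population config")
        for site, _region in self.sites:
            counts = self.haplotype_counts.get(site)
            freqs = self.haplotype_frequencies.get(site)
            if (counts is None) == (freqs is None):
                raise ValueError(
                    f"site {site!r}: exactly one of counts/frequencies required")
            table = counts if counts is not None else freqs
            for hap in table:
                if hap not in catalog:
                    raise ValueError(f"site {site!r}: unknown haplotype {hap!r}")
            if counts is not None:
                if sum(counts.values()) < 1:
                    raise ValueError(f"site {site!r}: needs at least 1 colony")
            else:
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"site {site!r}: frequencies sum to {total}, not 1")
                if self.n_colonies.get(site, 0) < 1:
                    raise ValueError(f"site {site!r}: n_colonies must be >= 1")


def default_population_config(seed: int = 0) -> PopulationConfig:
    """The 512-colony, 15-site survey composition (deterministic counts)."""
    comp = load_default_composition()
    sites: list[tuple[str, str]] = []
    counts: dict[str, dict[str, int]] = {}
    for (site, region), sub in comp.groupby(["site", "region"], sort=False):
        sites.append((site, region))
        counts[site] = dict(zip(sub["haplotype"], sub["count"]))
    return PopulationConfig(sites=sites, haplotype_counts=counts, seed=seed)


# ---------------------------------------------------------------------------
# Amplicon construction
# ---------------------------------------------------------------------------

def build_amplicon(spec: ArchitectureSpec,
                   family_subs: dict[int, str] | None = None) -> str:
    """Assemble one amplicon sequence from an architecture spec.

    The first two Q copies live on the master alignment (so variant edits can
    address them by column); additional tandem copies are inserted unmodified
    between the second Q and the cox2 fragment.
    """
    n_q_aln = min(spec.n_q, 2)
    row = grammar.aligned_row(spec.p_form, n_q_aln, spec.sublineage_template,
                              family_subs)
    try:
        row = grammar.apply_edits(row, spec.variant_edits)
    except ValueError as exc:
        raise ValueError(f"variant edit outside this architecture: {exc}") from exc
    seq = grammar.degap(row)
    if spec.n_q > 2:
        cox2 = grammar.TEMPLATES["cox2"]
        assert seq.endswith(cox2)
        extra = grammar.TEMPLATES["q"] * (spec.n_q - 2)
        seq = seq[:-len(cox2)] + extra + cox2
    return seq


def catalog_amplicon(catalog: HaplotypeCatalog, name: str) -> str:
    """Amplicon sequence of a named catalog haplotype."""
    return catalog.sequence(name)


def expected_length(p_form: str, n_q: int) -> int:
    """Closed-form amplicon length for an architecture (no variant edits)."""
    p_len = {"P0": grammar.P0_LEN, "P": grammar.P0_LEN - 13,
             "P1": grammar.P0_LEN - 15, "P2": grammar.P0_LEN - 18,
             "absent": 0}[p_form]
    return grammar.TRNA_LEN + p_len + n_q * grammar.Q_LEN + grammar.COX2_LEN


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def generate_population(config: PopulationConfig, catalog: HaplotypeCatalog
                        ) -> tuple[list[tuple[str, str]], pd.DataFrame, pd.DataFrame]:
    """Simulate a survey: returns (FASTA records, sample sheet, truth table).

    Deterministic under a fixed config and seed.  Sites in deterministic
    count mode enumerate their composition exactly; frequency-mode sites draw
    colony haplotypes from a multinomial with the configured probabilities.
    """
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str]] = []
    sheet_rows = []
    truth_rows = []
    counter = 0
    for site, region in config.sites:
        counts = config.haplotype_counts.get(site)
        if counts is not None:
            assignment = [h for h, c in counts.items() for _ in range(c)]
        else:
            freqs = config.haplotype_frequencies[site]
            names = list(freqs)
            draw = rng.multinomial(config.n_colonies[site],
                                   [freqs[n] for n in names])
            assignment = [n for n, c in zip(names, draw) for _ in range(c)]
        for hap in assignment:
            counter += 1
            sid = f"col{counter:04d}"
            rec = catalog.get(hap)
            records.append((sid, catalog.sequence(hap)))
            sheet_rows.append({"sample_id": sid, "site": site, "region": region})
            truth_rows.append({"sample_id": sid, "haplotype": hap,
                               "lineage": rec.lineage,
                               "sublineage": rec.sublineage,
                               "pattern": rec.pattern})
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "site", "region"])
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, sheet, truth


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_noise(records: list[tuple[str, str]], sub_rate: float, seed: int
              ) -> tuple[list[tuple[str, str]], int]:
    """Apply random point substitutions at the given per-base rate.

    Substitutions never fall inside an existing DraI motif and are rejected
    when they would create a new one, so the restriction-site diagnostics stay
    interpretable; this is a documented limitation of the noise model.
    Returns (noisy records, number of substitutions applied).
    """
    if not 0.0 <= sub_rate <= 0.02:
        raise ValueError("sub_rate must be within [0, 0.02]")
    if sub_rate == 0.0:
        return list(records), 0
    rng = np.random.default_rng(seed)
    out = []
    n_subs = 0
    for rid, seq in records:
        chars = list(seq)
        protected: set[int] = set()
        start = seq.find(grammar.DRAI_MOTIF)
        while start != -1:
            protected.update(range(start, start + 6))
            start = seq.find(grammar.DRAI_MOTIF, start + 1)
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for pos in hits:
            if pos in protected:
                continue
            old = chars[pos]
            alts = [b for b in "ACGT" if b != old]
            new = alts[int(rng.integers(3))]
            chars[pos] = new
            lo, hi = max(0, pos - 5), min(len(chars), pos + 6)
            if grammar.DRAI_MOTIF in "".join(chars[lo:hi]):
                chars[pos] = old  # would forge a restriction site; skip
            else:
                n_subs += 1
        out.append((rid, "".join(chars)))
    return out, n_subs
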