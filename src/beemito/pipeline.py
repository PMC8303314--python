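"""End-to-end pipeline: simulate/read -> type -> summarize -> differentiate
-> tree/network, as one reproducible run with a manifest.

A run is driven by a :class:`RunConfig` (built directly or from a JSON
config file) and writes plain-text outputs into the run directory: the
typing table, lineage/sub-lineage proportion summary, per-site diversity
table, PhiPT matrix and PCoA coordinates, the in-silico DraI digest table,
the NJ tree (Newick) and the median-joining network (edge/node TSVs), plus
``manifest.json`` recording versions, seeds and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import __version__, diversity, mitotyping, netphylo, refdata, seqsim

log = logging.getLogger("beemito.pipeline")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 1 territory)."""


@dataclass
class RunConfig:
    output_dir: str
    # exactly one input mode: a FASTA+sample sheet, or a simulation
    input_fasta: str | None = None
    sample_sheet: str | None = None
    simulate: bool = False
    composition: str | None = None      # TSV overriding the default survey
    noise_rate: float = 0.0
    seed: int = 0
    # stage toggles and knobs
    run_digest: bool = True
    run_tree: bool = True
    run_network: bool = True
    n_permutations: int = 999
    n_bootstrap: int = 1000
    upweight: int = netphylo.UPWEIGHT
    epsilon: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        has_fasta = self.input_fasta is not None
        if has_fasta == self.simulate:
            raise ConfigError(
                "exactly one of input_fasta / simulate must be given")
        if has_fasta and self.sample_sheet is None:
            raise ConfigError("input_fasta requires a sample_sheet")
        if not 0.0 <= self.noise_rate <= 0.02:
            raise ConfigError("noise_rate must be within [0, 0.02]")


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Proportion summary
# ---------------------------------------------------------------------------

def proportion_summary(typing_df: pd.DataFrame) -> pd.DataFrame:
    """Lineage and (within lineage A) sub-lineage composition, overall and
    per region: counts plus percentages rounded half-up to one decimal."""
    rows = []

    def block(scope: str, sub: pd.DataFrame) -> None:
        n = len(sub)
        for lineage, cnt in sub["lineage"].value_counts().items():
            rows.append({"scope": scope, "level": "lineage", "label": lineage,
                         "count": int(cnt),
                         "percent": round_half_up(100.0 * cnt / n)})
        a_sub = sub[sub["lineage"] == "A"]
        if len(a_sub):
            for sl, cnt in a_sub["sublineage"].value_counts().items():
                rows.append({"scope": scope, "level": "sublineage_within_A",
                             "label": sl, "count": int(cnt),
                             "percent": round_half_up(100.0 * cnt / len(a_sub))})
        for hap, cnt in sub["haplotype"].value_counts().items():
            rows.append({"scope": scope, "level": "haplotype", "label": hap,
                         "count": int(cnt),
                         "percent": round_half_up(100.0 * cnt / n)})

    block("overall", typing_df)
    for region, sub in typing_df.groupby("region", sort=False):
        block(region, sub)
    return pd.DataFrame(rows, columns=["scope", "level", "label", "count",
                                       "percent"])


def check_pattern_consistency(typing_df: pd.DataFrame) -> None:
    """Structural bookkeeping asserted on every run: P0-prefixed patterns
    must coincide with sub-lineage AI calls, P1-prefixed with AIII,
    P-element-less with lineage C and the M-form with lineage M."""
    pat = typing_df["pattern"]
    p0 = pat.str.startswith("P0").sum()
    p1 = pat.str.startswith("P1").sum()
    c = (~pat.str.contains("P")).sum()
    m = (pat.str.startswith("P") & ~pat.str.startswith(("P0", "P1", "P2"))).sum()
    ai = (typing_df["sublineage"] == "AI").sum()
    aiii = (typing_df["sublineage"] == "AIII").sum()
    lc = (typing_df["lineage"] == "C").sum()
    lm = (typing_df["lineage"] == "M").sum()
    problems = []
    if p0 != ai:
        problems.append(f"P0-pattern colonies ({p0}) != sub-lineage AI ({ai})")
    if p1 != aiii:
        problems.append(f"P1-pattern colonies ({p1}) != sub-lineage AIII ({aiii})")
    if c != lc:
        problems.append(f"P-less colonies ({c}) != lineage C ({lc})")
    if m != lm:
        problems.append(f"P-form colonies ({m}) != lineage M ({lm})")
    if problems:
        raise RuntimeError("pattern/lineage bookkeeping failed: "
                           + "; ".join(problems))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = refdata.load_reference_catalog()
    manifest: dict = {
        "tool": "beemito",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    # ---- stage 1: obtain sequences -------------------------------------
    if config.simulate:
        if config.composition:
            comp = pd.read_csv(config.composition, sep="\t")
            sites, counts = [], {}
            for (site, region), sub in comp.groupby(["site", "region"],
                                                    sort=False):
                sites.append((site, region))
                counts[site] = dict(zip(sub["haplotype"], sub["count"]))
            pop = seqsim.PopulationConfig(sites=sites, haplotype_counts=counts,
                                          seed=config.seed)
        else:
            pop = seqsim.default_population_config(seed=config.seed)
        records, sheet, truth = seqsim.generate_population(pop, catalog)
        if config.noise_rate > 0:
            records, n_subs = seqsim.add_noise(records, config.noise_rate,
                                               seed=config.seed + 1)
            manifest["stages"]["noise"] = {"substitutions": n_subs}
        refdata.write_fasta(records, out / "amplicons.fasta")
        refdata.write_sample_sheet(sheet, out / "sample_sheet.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["inputs"]["mode"] = "simulation"
    else:
        records = refdata.read_fasta(config.input_fasta)
        sheet = refdata.read_sample_sheet(config.sample_sheet)
        missing = {rid for rid, _ in records} - set(sheet["sample_id"])
        if missing:
            raise ConfigError(
                f"samples missing from sample sheet: {sorted(missing)[:5]}")
        manifest["inputs"] = {
            "mode": "fasta",
            "fasta_sha256": _sha256(Path(config.input_fasta)),
            "sample_sheet_sha256": _sha256(Path(config.sample_sheet)),
        }
    log.info("stage=input n_sequences=%d", len(records))
    manifest["stages"]["input"] = {"n_sequences": len(records)}

    # ---- stage 2: typing ------------------------------------------------
    results = mitotyping.type_sequences(records, catalog, sheet)
    refdata.write_typing_table(results, out / "typing.tsv")
    typing_df = refdata.read_typing_table(out / "typing.tsv")
    check_pattern_consistency(typing_df)
    log.info("stage=typing n_rows=%d", len(typing_df))
    manifest["stages"]["typing"] = {
        "n_rows": len(typing_df),
        "n_novel": int(sum(r.novel for r in results)),
    }

    # ---- stage 3: proportions ------------------------------------------
    summary = proportion_summary(typing_df)
    summary.to_csv(out / "proportions.tsv", sep="\t", index=False)
    manifest["stages"]["proportions"] = {"n_rows": len(summary)}

    # ---- stage 4: diversity --------------------------------------------
    pop_table = diversity.population_table(typing_df)
    site_regions = dict(zip(typing_df["site"], typing_df["region"]))
    summaries = diversity.diversity_summary(pop_table)
    div_df = diversity.summaries_to_frame(summaries, site_regions)
    div_df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    manifest["stages"]["diversity"] = {"n_sites": len(div_df)}

    # ---- stage 5: PhiPT + PCoA -----------------------------------------
    labels = typing_df.apply(
        lambda r: f"{r.lineage}-{r.sublineage}" if r.lineage == "A"
        else r.lineage, axis=1)
    phi = diversity.phi_pt(labels, typing_df["site"],
                           n_permutations=config.n_permutations,
                           seed=config.seed + 2)
    phi.pairwise.to_csv(out / "phipt_matrix.tsv", sep="\t")
    if phi.pairwise_p is not None:
        phi.pairwise_p.to_csv(out / "phipt_pvalues.tsv", sep="\t")
    ord_res = diversity.pcoa(phi.pairwise)
    coords = ord_res.coordinates.copy()
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame({
        "axis": [f"axis{i+1}" for i in range(len(ord_res.percent_variance))],
        "percent_variance": [round(p, 2) for p in ord_res.percent_variance],
    }).to_csv(out / "pcoa_variance.tsv", sep="\t", index=False)
    manifest["stages"]["differentiation"] = {
        "phi_pt": round(phi.phi_pt, 4),
        "p_value": phi.p_value,
        "pcoa_axis1_percent": round(float(ord_res.percent_variance[0]), 2)
        if len(ord_res.percent_variance) else None,
    }

    # ---- stage 6: DraI digest ------------------------------------------
    if config.run_digest:
        with open(out / "dra1_digest.tsv", "w") as fh:
            fh.write("sample_id\tfragment_lengths\n")
            for rid, seq in records:
                frags = mitotyping.insilico_dra1_digest(seq)
                fh.write(f"{rid}\t{','.join(map(str, frags))}\n")
        manifest["stages"]["digest"] = {"n_rows": len(records)}

    # ---- stage 7: tree and network -------------------------------------
    if config.run_tree or config.run_network:
        matrix = netphylo.encode_characters(catalog, include_outgroup=True,
                                            upweight=config.upweight)
        netphylo.write_character_matrix(matrix, out / "characters.tsv")
    if config.run_tree:
        newick = netphylo.nj_bootstrap_tree(
            matrix, n_bootstrap=config.n_bootstrap, seed=config.seed + 3,
            outgroup=catalog.outgroup_name)
        (out / "nj_tree.nwk").write_text(newick + "\n")
        manifest["stages"]["tree"] = {"n_bootstrap": config.n_bootstrap}
    if config.run_network:
        net_matrix = netphylo.encode_characters(
            catalog, include_outgroup=False, upweight=config.upweight)
        network = netphylo.median_joining_network(net_matrix,
                                                  epsilon=config.epsilon)
        netphylo.attach_frequencies(network, typing_df)
        netphylo.write_network(network, out / "network_edges.tsv",
                               out / "network_nodes.tsv")
        manifest["stages"]["network"] = {
            "n_nodes": len(network.nodes),
            "n_median_vectors": sum(
                1 for a in network.nodes.values() if a["kind"] == "median"),
            "n_edges": len(network.edges),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("stage=done output_dir=%s", out)
    return manifest
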