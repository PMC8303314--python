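"""Regenerate the shipped package-data files under src/beemito/data/.

The catalog TSV + aligned FASTA are deterministic functions of the element
grammar; this script exists so the shipped files can be rebuilt and diffed
after any intentional change to the grammar or catalog definitions.

Run from the repository root:  python scripts/build_reference_data.py
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from beemito.refdata import build_catalog, write_catalog_data  # noqa: E402


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "beemito" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    cat = build_catalog()
    write_catalog_data(cat, data_dir)
    print(f"wrote catalog ({len(cat.records)} records) to {data_dir}")


if __name__ == "__main__":
    main()
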