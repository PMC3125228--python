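"""Regenerate the bundled synthetic reference FASTA.

Usage:  python scripts/make_reference_fixture.py
Writes src/mitosoma/data/rcrs_synthetic.fasta (deterministic).
"""

from pathlib import Path

from mitosoma.reference import bundled_annotation
from mitosoma._synthref import build_synthetic_reference


def main() -> None:
    annotation = bundled_annotation()
    ref = build_synthetic_reference(annotation)
    out = Path(__file__).resolve().parents[1] / "src" / "mitosoma" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "rcrs_synthetic.fasta"
    with open(path, "w") as fh:
        fh.write(">rCRS-synthetic synthetic stand-in, rCRS coordinates, 16569 bp\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    print(f"wrote {path} ({len(ref.sequence)} bp)")


if __name__ == "__main__":
    main()
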