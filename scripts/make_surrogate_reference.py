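"""Build the packaged synthetic mitochondrial reference surrogate.

Provenance tool, not part of the analysis pipeline. It takes a real human
mitochondrial genome FASTA (GenBank NC_001807.4, 16,571 bp) and removes one
base from each of the two hypervariable control-region poly-C runs (near
positions 306 and 16184), yielding a 16,569-bp circle on which all 13
protein-coding genes sit at the standard rCRS annotation coordinates with
intact reading frames. The output is a SYNTHETIC SURROGATE for the rCRS:
coding content is real human mtDNA, but the sequence as a whole is not the
rCRS and must not be used as a clinical/population reference.

Usage:
    python scripts/make_surrogate_reference.py NC_001807.fasta out.fa
"""

import sys

from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN_GENES = {
    "MT-ND1": (3307, 4262, "+"), "MT-ND2": (4470, 5511, "+"),
    "MT-CO1": (5904, 7445, "+"), "MT-CO2": (7586, 8269, "+"),
    "MT-ATP8": (8366, 8572, "+"), "MT-ATP6": (8527, 9207, "+"),
    "MT-CO3": (9207, 9990, "+"), "MT-ND3": (10059, 10404, "+"),
    "MT-ND4L": (10470, 10766, "+"), "MT-ND4": (10760, 12137, "+"),
    "MT-ND5": (12337, 14148, "+"), "MT-ND6": (14149, 14673, "-"),
    "MT-CYB": (14747, 15887, "+"),
}


def build(seq: str) -> str:
    if len(seq) != 16571:
        raise SystemExit(f"expected a 16,571-bp NC_001807 sequence, got {len(seq)}")
    i1 = seq.index("AAACCCCCCCC", 290) + 3
    out = seq[:i1] + seq[i1 + 1:]
    i2 = out.index("AAACCCCCCCC", 16150) + 3
    out = out[:i2] + out[i2 + 1:]
    assert len(out) == 16569
    for name, (start, end, strand) in PROTEIN_GENES.items():
        sub = out[start - 1:end]
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
        prot = str(Seq(sub[: len(sub) // 3 * 3]).translate(table=2))
        if "*" in prot[:-1]:
            raise SystemExit(f"{name}: internal stop after adjustment")
    return out


def main() -> None:
    src, dst = sys.argv[1], sys.argv[2]
    # tolerate old Pearson-style ';' comment lines some FASTA archives carry
    with open(src) as fh:
        lines = [ln for ln in fh if not ln.startswith(";")]
    import io

    rec = next(SeqIO.parse(io.StringIO("".join(lines)), "fasta"))
    seq = build(str(rec.seq).upper())
    with open(dst, "w") as fh:
        fh.write(
            ">mito_surrogate synthetic human mtDNA reference surrogate "
            "(NC_001807-derived, rCRS coordinate layout, 16569 bp)\n"
        )
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


if __name__ == "__main__":
    main()
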