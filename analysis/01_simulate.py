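#!/usr/bin/env python
"""Generate the synthetic study data set with known ground truth.

Writes the genome FASTA, CDS annotation GFF3, per-base 6mA calls,
differential-expression table, the reference/test Hi-C contact pair and
the truth table under results/synthetic/.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from methylhic import io_formats, synthgen

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = synthgen.SynthConfig(seed=SEED)
    data = synthgen.generate_all(config)

    io_formats.write_fasta(OUT / "genome.fasta", [data["genome"]])
    io_formats.write_gff3(OUT / "annotation.gff3", data["annotation"])
    io_formats.write_mods_gff(OUT / "modifications.gff", data["calls"])
    data["de_table"].to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    n = config.hic_bins
    iu = np.triu_indices(n)
    for name, mat in (("hic_ref", data["hic_ref"]), ("hic_test", data["hic_test"])):
        pairs = [
            (int(i), int(j), int(c)) for i, j, c in zip(iu[0], iu[1], mat[iu]) if c > 0
        ]
        io_formats.write_contacts(OUT / f"{name}.tsv", pairs)
    truth = {
        "methylation": data["meth_truth"].to_dict(),
        "hic": data["hic_truth"].to_dict(),
        "de": data["de_truth"].to_dict(),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=1))

    ann = data["annotation"]
    print(f"seed {SEED}: {config.genome_length / 1000:.0f} kb genome, "
          f"{len(ann.genes)} CDS, {len(data['calls'])} 6mA calls "
          f"({len(data['meth_truth'].motif_instances)} planted motif instances), "
          f"{n}x{n} Hi-C pair, {len(data['de_truth'].de_gene_ids)} DE genes")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
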