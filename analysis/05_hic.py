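#!/usr/bin/env python
"""Comparative Hi-C between the reference and test conditions.

Reads the contact pair written by 01_simulate.py, balances both maps,
calls significant interactions (p < 0.01, q < 0.01, count > 2), detects
CIDs from insulation minima, derives the condition-unique interactions,
CIDs and insulation regions, maps them to genes, and asks whether the
planted functional category is enriched among region genes.  Writes
unique_interactions.tsv, cids_<cond>.bed and unique_insulation.bed under
results/.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from methylhic import enrich_stats, hic_compare, io_formats

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"
SYN = BASE / "synthetic"
N_BINS = 400
BIN_SIZE = 500  # 200 kb genome / 400 bins


def main() -> None:
    truth = json.loads((SYN / "truth.json").read_text())
    annotation = io_formats.read_gff3(SYN / "annotation.gff3", N_BINS * BIN_SIZE)
    stages = {}
    for cond in ("ref", "test"):
        raw = hic_compare.bin_contacts(
            io_formats.read_contacts(SYN / f"hic_{cond}.tsv"), N_BINS, BIN_SIZE
        )
        bal, _ = hic_compare.ice_balance(raw)
        sig = hic_compare.call_significant(raw, bal)
        prof = hic_compare.insulation_profile(bal)
        cids = hic_compare.call_cids(prof)
        stages[cond] = (sig, prof, cids)
        with open(BASE / f"cids_{cond}.bed", "w") as fh:
            for c in cids:
                fh.write(f"chr\t{c.start * BIN_SIZE}\t{c.end * BIN_SIZE}\tCID\n")
        print(f"{cond}: {len(sig)} significant interactions, {len(cids)} CIDs "
              f"(boundaries at {sorted(c.start % N_BINS for c in cids)})")

    uniq = hic_compare.unique_elements(
        stages["ref"][0], stages["test"][0], stages["ref"][2], stages["test"][2]
    )
    regions = hic_compare.unique_insulation_regions(stages["ref"][1], stages["test"][1])
    pd.DataFrame(uniq["interactions_unique_b"], columns=["bin_i", "bin_j"]).to_csv(
        BASE / "unique_interactions.tsv", sep="\t", index=False
    )
    with open(BASE / "unique_insulation.bed", "w") as fh:
        for iv in regions:
            fh.write(f"chr\t{iv.start * BIN_SIZE}\t{iv.end * BIN_SIZE}\tunique_insulation\n")

    planted = {tuple(p[:2]) for p in truth["hic"]["diff_contacts"]}
    got = set(uniq["interactions_unique_b"])
    print(f"unique to test: {len(got)} interactions "
          f"({len(planted & got)}/{len(planted)} planted recovered), "
          f"{len(uniq['cids_unique_b'])} CIDs, {len(regions)} insulation regions")
    extra = truth["hic"]["cid_boundaries_test_extra"][0]
    covered = any((extra - r.start) % N_BINS < r.length for r in regions)
    print(f"planted test-only boundary at bin {extra} covered by unique "
          f"insulation regions: {covered}")

    # genes inside the unique elements, and category enrichment among them
    from methylhic.io_formats import Interval

    pair_regions = [Interval(min(i, j), min(i, j) + 1) for i, j in got] + [
        Interval(max(i, j), max(i, j) + 1) for i, j in got
    ]
    genes_interactions = hic_compare.genes_in_regions(pair_regions, BIN_SIZE, annotation)
    genes_insulation = hic_compare.genes_in_regions(regions, BIN_SIZE, annotation)
    print(f"genes in unique-interaction bins: {len(genes_interactions)}; "
          f"in unique insulation regions: {len(genes_insulation)}")
    if genes_interactions:
        rows = enrich_stats.category_enrichment(genes_interactions, annotation, key="cog")
        top = min(rows, key=lambda r: r.p)
        print(f"most enriched category among interaction genes: "
              f"[{top.category}] p = {top.p:.3f}")


if __name__ == "__main__":
    main()
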