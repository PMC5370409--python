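#!/usr/bin/env python
"""Run the full three-track analysis on the twelve ciliate mitochondrial
genomes (requires the GenBank files fetched by fetch_real_data.py).

Prints and saves: the number of conserved elements and the
presence/absence matrix with its distance tree; per-genome protein
counts, cluster/singleton totals and the wide-cluster selection; the
Nad9 paralog divergence report; and the chromosome-structure distance
tree with its ancestral gene-order reconstruction.

Usage:
    python scripts/real_data_analysis.py --data data/real --out results/real
"""

import argparse
import sys
from pathlib import Path

from mitevol.chromosome import distance_matrix
from mitevol.genome_io import (
    extract_structure,
    read_genbank,
    write_gene_orders,
    write_matrix,
    write_newick,
)
from mitevol.hce import HceParams, find_hces, scan_consensus
from mitevol.proteins import (
    ProteinRecord,
    cluster,
    cluster_stats,
    count_differences,
    find_paralog_pairs,
    pairwise_hits,
    select_wide_clusters,
)
from mitevol.reconstruct import reconstruct
from mitevol.trees import binary_distance, neighbor_joining


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("data/real"))
    ap.add_argument("--out", type=Path, default=Path("results/real"))
    args = ap.parse_args(argv)
    paths = sorted(args.data.glob("*.gb"))
    if len(paths) < 2:
        print(f"no GenBank files under {args.data}; run fetch_real_data.py first",
              file=sys.stderr)
        return 1
    args.out.mkdir(parents=True, exist_ok=True)
    genomes = [read_genbank(p) for p in paths]
    print(f"{len(genomes)} genomes loaded")

    # --- track 1: conserved elements
    hces, matrix = find_hces(genomes, HceParams())
    print(f"conserved elements found: {len(hces)}")
    print(f"presence matrix: {matrix.shape[0]} x {matrix.shape[1]}")
    write_matrix(matrix, args.out / "hce_matrix.tsv")
    if matrix.shape[1] >= 1 and matrix.shape[0] >= 3:
        tree = neighbor_joining(binary_distance(matrix, "hamming"))
        write_newick(tree, args.out / "hce_tree.nwk")
    n_with_promoter = sum(
        1 for h in hces if scan_consensus(h.consensus, "YRTA"))
    print(f"elements with a YRTA promoter core in their consensus: "
          f"{n_with_promoter}")

    # --- track 2: protein families
    proteins = []
    for g in genomes:
        for i, f in enumerate(g.proteins()):
            if f.translation:
                proteins.append(ProteinRecord(f"{g.accession}_{i:03d}",
                                              g.accession, f.gene_id,
                                              f.translation))
    print(f"proteins: {len(proteins)}")
    clusters = cluster(pairwise_hits(proteins), proteins)
    nontrivial = sum(1 for c in clusters if c.nontrivial)
    singles = len(clusters) - nontrivial
    print(f"nontrivial clusters: {nontrivial}; singletons: {singles}")
    table, hist = cluster_stats(clusters)
    print(table.to_string())
    print(f"cluster width histogram: {hist}")
    wide = select_wide_clusters(clusters, 6)
    print(f"clusters covering >= 6 species: {len(wide)}")
    table.to_csv(args.out / "cluster_stats.tsv", sep="\t")
    for cid, genome, p1, p2, diff in find_paralog_pairs(clusters):
        print(f"paralog pair in cluster {cid} ({genome}): {p1} vs {p2} "
              f"differ at {diff} positions")
    # cross-genome divergence of within-genome duplicate pairs
    for c in clusters:
        by_genome = {}
        for m in c.members:
            by_genome.setdefault(m.genome, []).append(m)
        dups = {g: ms for g, ms in by_genome.items() if len(ms) > 1}
        if len(dups) >= 2:
            gs = sorted(dups)
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    for a in dups[gs[i]]:
                        for b in dups[gs[j]]:
                            print(f"cluster {c.cluster_id}: {a.protein_id} vs "
                                  f"{b.protein_id}: "
                                  f"{count_differences(a, b)} positions")

    # --- track 3: chromosome structures
    structures = {g.accession: extract_structure(g) for g in genomes}
    write_gene_orders(structures, args.out / "gene_orders.tsv")
    m = distance_matrix(structures)
    m.to_tsv(args.out / "chrom_distances.tsv")
    tree = neighbor_joining(m)
    write_newick(tree, args.out / "chrom_tree.nwk")
    print("chromosome-structure tree written")
    scenario = reconstruct(tree, structures)
    (args.out / "reconstruction.tsv").write_text(scenario.to_table())
    (args.out / "reconstruction.json").write_text(scenario.to_json())
    print(f"ancestral reconstruction total cost: {scenario.total_cost:.2f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
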