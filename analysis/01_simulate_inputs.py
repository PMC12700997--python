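#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Produces, under results/synthetic/:
  - dimorphic.tsv / monomorphic.tsv  tracked division lineages (the first
    with a 30-min differentiation delay and off-center division, the
    second delay-free and mid-cell dividing);
  - tree.nwk / matrix.tsv / matrix_truth.json  a 200-tip species tree with
    a planted 26-family loss module in two independent clades over 2000
    conserved background families (1% sporadic loss, 95% conservation);
  - annotations.tsv / pgc_truth.json  a 20-genome cohort where 2 genomes
    carry a photosynthesis gene cluster with CBB genes, plus one genome
    with the cluster split across a contig edge.
"""

import argparse
import json
from pathlib import Path

from caulotraits import io as cio
from caulotraits import (
    DimorphicParams,
    PlantedLossSpec,
    PlantedPGCSpec,
    simulate_annotated_genomes,
    simulate_lineage,
    simulate_loss_matrix,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    dimorphic = simulate_lineage(
        DimorphicParams(duration=700, n_founders=10, seed=args.seed)
    )
    cio.write_lineage(dimorphic, out / "dimorphic.tsv")
    monomorphic = simulate_lineage(
        DimorphicParams(
            swarmer_delay_mean=0, swarmer_delay_cv=0, division_offset=0,
            duration=700, n_founders=10, seed=args.seed,
        )
    )
    cio.write_lineage(monomorphic, out / "monomorphic.tsv")
    print(f"lineages: {len(dimorphic)} dimorphic / {len(monomorphic)} monomorphic cells")

    spec = PlantedLossSpec(
        n_tips=200, n_background_families=2000, background_conservation=0.95,
        sporadic_loss_rate=0.01, focal_clades=2, module_size=26, seed=args.seed,
    )
    tree, matrix, truth = simulate_loss_matrix(None, spec)
    cio.write_newick(tree, out / "tree.nwk")
    cio.write_matrix(matrix, out / "matrix.tsv")
    (out / "matrix_truth.json").write_text(
        json.dumps(
            {
                "module_families": sorted(truth.family_ids),
                "focal_lineages": sorted(truth.focal_lineages),
            },
            indent=2,
        )
    )
    print(
        f"matrix: {len(matrix.genome_ids)} genomes x {len(matrix.family_ids)} families,"
        f" module of {len(truth.family_ids)} planted in {len(truth.focal_lineages)} clades"
    )

    with_pgc, pgc_truth = simulate_annotated_genomes(
        PlantedPGCSpec(n_genomes=2, genes_per_genome=2000, with_cbb=True, seed=args.seed)
    )
    split, split_truth = simulate_annotated_genomes(
        PlantedPGCSpec(n_genomes=1, genes_per_genome=2000, split_at=13, seed=args.seed + 1)
    )
    plain, _ = simulate_annotated_genomes(
        PlantedPGCSpec(n_genomes=17, genes_per_genome=2000, pgc_gene_order=(), seed=args.seed + 2)
    )
    # re-key genomes so ids do not collide across the three batches
    cohort = []
    for prefix, batch in (("PGC", with_pgc), ("EDGE", split), ("BG", plain)):
        for i, ann in enumerate(batch):
            ann.genome_id = f"{prefix}{i:02d}"
            ann.genes = ann.genes.assign(
                genome_id=ann.genome_id,
                contig_id=ann.genes.contig_id.str.replace(r"^G\d+", ann.genome_id, regex=True),
            )
            cohort.append(ann)
    cio.write_annotations(cohort, out / "annotations.tsv")
    (out / "pgc_truth.json").write_text(
        json.dumps(
            [t.__dict__ for t in pgc_truth + split_truth], indent=2, default=str
        )
    )
    print(f"annotations: {len(cohort)} genomes (2 PGC+CBB, 1 contig-edge PGC, 17 background)")


if __name__ == "__main__":
    main()
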