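#!/usr/bin/env python
"""Reproduce the yeast segregant preprocessing counts from downloaded data.

The 109-segregant yeast cross (BY x RM, expression profiled under glucose
and ethanol; 4,482 genes, 2,956 genotyped loci) is distributed with its
original publication and is NOT bundled here.  Download it, convert the
expression matrices to the package's genes x samples TSV layout (one file
per condition, ``NA`` for missing) and the genotypes to the markers x
samples TSV plus a marker-interval TSV, then run::

    python scripts/reproduce_yeast.py \
        --expr-glucose glucose.tsv --expr-ethanol ethanol.tsv \
        --geno genotypes.tsv --intervals intervals.tsv

The script reports the preprocessing milestones of the full analysis:

* genes retained after dropping those with > 10 missing values in either
  condition (expected 4,419 of 4,482),
* merged markers at the fewer-than-5-discordant-calls rule (expected 820),
* marker pairs with every joint-genotype class holding >= 15 segregants
  (expected 305,301),
* merged markers at the post-scan fewer-than-15 rule (expected 266).

With ``--full-scan`` it additionally runs the exhaustive scan for one
condition.  Expect roughly a CPU-week per condition at yeast scale; the
preprocessing counts themselves take seconds.
"""

from __future__ import annotations

import argparse

from epicoex.config import ScanConfig
from epicoex.io import align_samples, read_expression_table, read_genotype_table
from epicoex.preprocess import (
    eligible_marker_pairs,
    filter_genes_by_missing,
    merge_markers,
    normal_quantile_transform,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--expr-glucose", required=True)
    parser.add_argument("--expr-ethanol", required=True)
    parser.add_argument("--geno", required=True)
    parser.add_argument("--intervals", required=True)
    parser.add_argument("--full-scan", action="store_true",
                        help="also run the exhaustive scan (very slow)")
    parser.add_argument("--condition", default="glucose",
                        choices=["glucose", "ethanol"],
                        help="condition used for --full-scan")
    args = parser.parse_args()

    cfg = ScanConfig()
    glu = read_expression_table(args.expr_glucose, condition_label="glucose")
    eth = read_expression_table(args.expr_ethanol, condition_label="ethanol")
    geno = read_genotype_table(args.geno, args.intervals)
    glu, geno = align_samples(glu, geno)
    eth, _ = align_samples(eth, geno)

    glu, eth = filter_genes_by_missing([glu, eth], cfg.max_missing_per_gene)
    print(f"genes retained after missing-value filter: {glu.n_genes} (expected 4419)")

    merged, _ = merge_markers(geno, cfg.marker_merge_discordance)
    print(f"merged markers (< {cfg.marker_merge_discordance} discordant): "
          f"{merged.n_markers} (expected 820)")

    pairs = eligible_marker_pairs(merged, cfg.min_class_size)
    print(f"eligible marker pairs (all classes >= {cfg.min_class_size}): "
          f"{len(pairs)} (expected 305301)")

    post, _ = merge_markers(merged, cfg.module_merge_discordance)
    print(f"post-scan merged markers (< {cfg.module_merge_discordance} "
          f"discordant): {post.n_markers} (expected 266)")

    if args.full_scan:
        from epicoex.scan import exhaustive_scan, results_to_frame

        expr = normal_quantile_transform(glu if args.condition == "glucose" else eth)
        results = exhaustive_scan(expr, merged, cfg)
        frame = results_to_frame(results, merged)
        out = f"yeast_scan_{args.condition}.tsv"
        frame.to_csv(out, sep="\t", index=False)
        n_sig = sum(r.significant for r in results)
        print(f"significant modules ({args.condition}): {n_sig}; results in {out}")


if __name__ == "__main__":
    main()
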