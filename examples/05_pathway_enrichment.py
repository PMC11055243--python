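"""Fisher-exact pathway enrichment of one pair's differential genes.

A pathway is planted with enrichment odds 5 toward decreased
expression; the per-pair, per-direction Fisher test with BH-FDR should
flag it and leave the unplanted pathways alone.
"""

import pairhmm as ph

chrom = {"1": 1500, "2": 1500}
genes = ph.make_annotation(chrom).index
pathways = ph.make_pathways(genes, n_pathways=10, size=150, seed=3)
force = ph.planted_force_prob(5.0, ph.default_generative_parameters())

cfg = ph.SimulationConfig(
    n_patients=4, pairs_per_patient=(1, 1, 1, 1), chromosome_lengths=chrom,
    pathway_effects={"pw01": ("-", force)}, seed=4,
)
cohort = ph.simulate_cohort(cfg, pathways=pathways)
profiles = ph.compute_pair_profiles(cohort.expression, cohort.pairs,
                                    cohort.annotation)
decodings = [ph.decode_states(cfg.params, p) for p in profiles]

table = ph.enrich_all_pairs(decodings, pathways, genes, alpha=0.05)
sig = table[table["significant"]]
print(table.head(4)[["pair_id", "pathway_id", "direction", "k", "K", "n",
                     "odds_ratio", "p", "q"]].to_string(index=False))
print(f"\nsignificant rows (q < 0.05): {len(sig)}")
print(sig[["pair_id", "pathway_id", "direction", "q"]].to_string(index=False))
print("\nOnly the planted pathway pw01 reaches significance, and only in "
      "the planted '-' direction (isolated planted genes can fall short "
      "of q < 0.05 in an individual pair, as for the first pair here).")
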