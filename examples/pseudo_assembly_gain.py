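"""The pseudo-assembly effect on genus-conserved genomes.

Two genera of three species each share 80% of their genomes within the
genus; reads are sampled from one species per genus.  A read from a
conserved region aligns equally well to all three genus members, so on
its own it can only be classified to the genus.  Chaining overlapping
alignments lets the sampled genome's chain extend into its unique 20%,
outscoring the siblings' conserved-only chains, and the fractional score
cutoff then removes them before the LCA.
"""

from seedtax import (
    Fragment,
    GenusGroup,
    RunConfig,
    SimConfig,
    classify,
    evaluate,
    simulate_genomes,
    simulate_reads,
)

cfg = SimConfig(rng_seed=7, genome_length=50_000,
                genus_groups=[GenusGroup(3, 0.8), GenusGroup(3, 0.8)],
                abundances=[0.5, 0, 0, 0.5, 0, 0],
                n_fragments=4000, sub_rate=0.005, indel_rate=0.0005)
refs, tree = simulate_genomes(cfg)
pairs, truth = simulate_reads(refs, cfg)
fragments = [Fragment(r1.id, r1, r2) for r1, r2 in pairs]

for label, on in (("with pseudo-assembly   ", True), ("without pseudo-assembly", False)):
    out = classify(refs, tree, fragments, RunConfig(pseudo_assembly=on))
    acc = evaluate(out.results, truth, tree)
    print(f"{label}: species {acc['species_accuracy']:.3f}  "
          f"genus {acc['genus_accuracy']:.3f}")

print()
print("Without chaining, conserved-region reads tie across the genus and")
print("drop to genus-level assignments; with chaining they recover the")
print("exact species.  Genus-level accuracy is unaffected in both modes.")
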