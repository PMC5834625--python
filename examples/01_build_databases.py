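"""Build pI-restricted six-frame databases from a synthetic genome.

Generates a toy genome with planted novel coding elements, runs the full
discovery-stage pipeline (six-frame translation, tryptic digestion,
known-peptide subtraction, pI partitioning) and builds the decoy companion
of one fraction database.
"""

from ipaw.db_builder import PartitionConfig, build_6ft_db, build_decoy_db
from ipaw.synthetic_fixtures import make_toy_genome

toy = make_toy_genome(seed=1)
print(f"toy genome: {sum(len(s) for s in toy.genome.values())} bp, "
      f"{len(toy.proteins)} known proteins")

per_fraction, unique, report = build_6ft_db(
    toy.genome, toy.proteins, fractions=range(72),
    config=PartitionConfig(margin=0.11, strip="IPG3-10"),
)
print(f"{report['n_unique']} unique novel peptides survive known subtraction")
print(f"{len(report['removed_exact'])} peptides removed as exact known matches")

# each peptide lands in every fraction whose pI window (+/- 0.11) contains it
non_empty = [f for f, entries in per_fraction.items()
             if any(len(s) <= 30 for s in entries.values())]
example = unique[0][0]
print(f"example: {example.sequence} at {example.chrom}:{example.blocks[0][0]}"
      f"({example.strand}) predicted pI {example.predicted_pi:.2f}")

targets = {f"p{i}": group[0].sequence for i, group in enumerate(unique)}
decoys, decoy_report = build_decoy_db(targets)
print(f"{len(decoys)} reversed-tryptic decoys "
      f"({len(decoy_report['self_decoys'])} self-palindromic)")
# The novel peptide count is the discovery-stage search space; every decoy
# keeps its target's C-terminal residue so the tryptic character matches.
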