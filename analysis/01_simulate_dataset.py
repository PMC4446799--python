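#!/usr/bin/env python
"""Generate the standard synthetic dataset: four gene families with planted
sex-chromosome-to-autosome transpositions, paired Y losses, and
tissue-stratified reads on the packaged 13-species dated tree.

Small tables go to results/sim/; bulky sequence/read files go to
scratch/sim/.  Every later driver regenerates the same dataset from the
same seed, so the files written here are for inspection, not plumbing.
"""

from pathlib import Path

from yrescue import io as yio
from yrescue import simulate as sim
from yrescue.fixtures import curated_tree

SEED = 1234
RESULTS = Path(__file__).resolve().parent.parent / "results" / "sim"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    tree = curated_tree()
    hom, synteny, reads, truth_events = sim.simulate_scenario(tree, SEED)
    yio.write_homolog_table(hom, RESULTS / "homologs.tsv")
    yio.write_synteny_table(synteny, RESULTS / "synteny.tsv")
    yio.write_fasta([(c.label, c.cds) for c in hom.entries if c.cds], SCRATCH / "cds.fasta")
    n_reads = 0
    for sp, rs in reads.items():
        yio.write_readset(rs, SCRATCH / f"reads_{sp}.fastq")
        n_reads += len(rs.reads)
    (RESULTS / "truth_events.tsv").write_text(
        "family\tbranch_id\n"
        + "".join(f"{f}\t{b}\n" for f, b in sorted(truth_events))
    )
    print(f"simulated {len(hom)} gene copies across {len(hom.species())} species")
    print(f"{n_reads} reads over {len(reads)} species")
    print(f"planted events: {sorted(truth_events)}")


if __name__ == "__main__":
    main()
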