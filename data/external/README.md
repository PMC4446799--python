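# External sequence data (not included)

The four published dN/dS reproduction tests in
`tests/test_acceptance.py` expect codon-aligned CDS pairs retrieved from
GenBank (the accession list is in the original study's supplementary
material and the sequences are not redistributed here):

- `EIF1A_mouse_rat.fasta` — mouse and rat autosomal EIF1A retrogene CDS
- `EIF2S3_human_squirrel_monkey.fasta` — human and squirrel monkey
  autosomal EIF2S3 retrogene CDS
- `RPS4_mouse_rat.fasta` — mouse and rat autosomal RPS4 retrogene CDS
- `UBA1_marmoset_squirrel_monkey.fasta` — marmoset autosomal UBA1 and
  squirrel monkey Y-linked UBA1 CDS

Each file: two records, equal length, codon-aligned (length divisible by
3, terminal stops stripped or left in place — the test strips nothing, so
strip terminal stops before saving). Without these files the four tests
fail with a message pointing here.
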