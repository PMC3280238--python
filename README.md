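# natx

Annotation and phylogenetic classification of long-chain sodium-channel
scorpion toxin (NaScTx) precursors:

* **synthdata** — synthetic toxin gene families with planted ground truth
  (family tree, conserved cysteine scaffold, signal peptides, C-terminal
  pro-sequences, error-bearing reads with qualities, mock vector).
* **est** — EST cleanup: sliding-window quality trimming (window 100 /
  Q20), vector masking, single-linkage contig/singlet clustering under the
  ">95 identical per 100" overlap rule.
* **precursor** — ORF finding, signal-peptide cleavage (explicit site or
  reference-anchored "auto"), C-terminal `G[KR]{1,3}` propeptide removal
  with amidation, alpha/beta candidate labelling.
* **masscalc** — average and monoisotopic peptide masses with disulfide
  (−2.016 Da/bridge) and amidation (−0.985 Da) corrections; greedy
  reconciliation against an experimental mass table.
* **align** — global pairwise alignment (affine gaps), reference-length
  percent identity, progressive multiple alignment with an NJ guide tree
  (or a user-supplied curated alignment), complete-deletion character
  matrix.
* **parsimony** — from-scratch maximum parsimony: Fitch scoring,
  random-addition starting trees, close-neighbor-interchange search,
  column bootstrap, majority-rule consensus with sub-50% collapse,
  outgroup rooting.
* **subfamily** — supported-clade subfamily extraction with singleton
  promotion, per-subfamily consensus sequences, systematic
  `NaTx<i>.<k>` nomenclature, reporting.
* **cli_pipeline** — `natx` CLI and an end-to-end runner with a single
  YAML config, derived per-stage seeds and a checksummed run manifest.

## CLI

```sh
natx simulate --subfamilies 4 --taxa-per 3 --seed 1 --out sim/
natx est --in sim/reads.fq --out est/
natx annotate --in sim/cds.fa --refs sim/true_matures.fa --out ann/
natx mass --in ann/matures.fa --exp table1.tsv --tol 1.5
natx align --in ann/matures.fa --out aln/           # or --user-aln curated.aln
natx mptree --matrix aln/matrix.phy --outgroup OUTG --reps 500 --seed 1 --out mp/
natx subfamilies --tree mp/consensus.nwk --aln aln/matures.aln --out sf/
natx run --seed 1 --out run/                        # all stages end-to-end
```

`natx --version` prints the package, residue-mass-table and config-schema
versions.

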