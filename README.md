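# quorumscan

A pipeline for discovering cytoplasmic peptide quorum-sensing (QS)
receptor–pheromone systems of the RRNPPA superfamily (Rap, Rgg, ComR, NprR,
PlcR, PrgX, AimR) in bacterial replicons, and for classifying each system's
pheromone architecture, export signal, genomic context and signaling role.

## What it does

- **`synthetic_data`** — generates replicons, gene tables, proteomes, MGE
  labels and a complete planted-truth record (receptor genes derived from
  per-family consensus models, flanking propeptide ORFs with n/h/c
  signal-peptide architecture, SPII lipobox variants, repeated and
  pseudorepeated mature peptides, sibling propeptide gene pairs, SHP-style
  small upstream peptides, eavesdropper systems, prophage/plasmid contexts).
  This replaces any dependence on external genome databases for development
  and testing.
- **`receptor_search`** — builds per-family position-specific log-odds
  profiles from seed alignments, calibrates score distributions against
  random decoys (Gumbel fit → E-values), scans proteomes with a local gapped
  dynamic-programming alignment, and applies coverage/E-value thresholds
  plus the family disambiguation rules (Rap+NprR double hits become NprR;
  Rgg candidates without a nearby propeptide are discarded).
- **`propeptide_finder`** — builds strand-aware flank windows (50 terminal
  bases of the receptor gene + 1,000 bases beyond, on each side), finds
  small ORFs (20–120 aa, ATG/GTG/TTG starts) on both strands, scores export
  signals with a documented heuristic (primary cutoff, then a relaxed 0.25
  fallback), and runs the family-specific routes: six-frame known-peptide
  matching upstream for Rgg/ComR (identity > 80%, coverage > 85%) and
  plasmid-wide matching for PrgX.
- **`repeat_analysis`** — propeptide length distributions with Tukey-fence
  outliers, detection of identical/pseudorepeated copies of the C-terminal
  5-mer, sibling propeptide comparison, Kruskal–Wallis tests.
- **`export_signal`** — first-40-column observed-count logo matrices,
  KK-duplet frequency, hydrophobicity profiles, conserved post-h-region
  residue tables, SPI/SPII pathway summaries and the MGE-enrichment
  goodness-of-fit chi-square.
- **`context_classifier`** — chromosome/prophage/plasmid/phage-plasmid
  context assignment (full containment for prophage intervals), signaling
  role classification (eavesdropper / single / chatterer / multi-message)
  and family × context summary tables.
- **`structure_compare`** — CA-only Kabsch superposition, pairwise RMSD
  matrices, thresholded interaction networks, UPGMA/neighbor-joining
  dendrograms (Newick, optional midpoint rooting) and greedy 95/95
  identity/coverage sequence clustering.

## Command-line interface

```bash
quorumscan simulate --seed 1 --out demo/                 # synthetic bundle + truth
quorumscan scan --genome-dir demo/ --out demo/hits.tsv   # receptor search
quorumscan propeptides --genome-dir demo/ --hits demo/hits.tsv --out demo/calls.tsv
quorumscan repeats --calls demo/calls.tsv --out demo/repeats.tsv
quorumscan exportsig --calls demo/calls.tsv --out demo/export.json
quorumscan classify --genome-dir demo/ --out-systems demo/systems.tsv \
    --out-summary demo/summary.tsv
quorumscan structcmp --structures pdbs/ --selections sel.tsv --out-prefix demo/tree
```

A genome bundle directory contains `replicons.fna`, `genes.gff3`,
`proteome.faa`, `mge.tsv`, `known_peptides.tsv` and `meta.json`; all
coordinates are 0-based half-open.

## Notes and caveats

- The signal-peptide score is a heuristic stand-in for neural predictors
  (n-region charge × h-region hydropathy × c-region cleavage terms, lipobox
  override for SPII); its 0.25 fallback cutoff applies to this score.
- Profile search uses uniform affine gap penalties rather than full
  profile-HMM insert/delete states; the decoy calibration absorbs the
  difference.
- The SHP (short hydrophobic peptide) gene model in the synthetic generator
  is a stand-in: short (<20 aa) upstream peptide genes without a canonical
  export signal.
- Per-family search thresholds default to E ≤ 1e-5 and coverage ≥ 0.6 and
  can be overridden per family.
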