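# scafeval

Evaluate how well a genome scaffolding run reproduces a known reference.
`scafeval` builds ordered, oriented contig layouts from standard inputs
(AGP v2.1, scaffold FASTA, MUMmer `show-coords` or PAF alignments) and
scores a proposed layout against a truth layout with five metrics:

* **edit distance** — minimum number of double-cut-and-join (DCJ)
  rearrangement operations separating the two layouts;
* **overall accuracy** — length fraction of contigs whose extremity
  pairings (neighbours / telomeres) agree in both layouts;
* **grouping accuracy** — length-weighted Jaccard agreement between
  scaffolds and chromosomes under an optimal one-to-one matching;
* **ordering accuracy** — length-weighted fraction of adjacent contig
  pairs in the assembly that are also adjacent in the reference;
* **orientation accuracy** — as ordering, additionally requiring
  consistent relative orientation.

Reports also carry the assembly N50 and a "no scaffolding" baseline in
which every contig is its own scaffold, so a scaffolder can be shown to
perform worse than doing nothing.

The package ships the generators needed to exercise all of this without
external data: seeded synthetic genomes (with optional repeat content and
haplotig-like redundant contigs), split-reference fragmentation at preset
piece sizes (10 kb – 1 Mb), Hi-C read-pair downsampling to a target
density in pairs per kilobase, and seeded rearrangement perturbation of a
truth layout with a known operation budget.

## Command-line usage

All commands log to stderr and write results to files, so outputs are
pipeable. Every run writes a metadata JSON that records inputs, seed and
thresholds.

```sh
# make a 2-chromosome synthetic genome
scafeval synth --n-chromosomes 2 --min-length 200000 --max-length 300000 \
    --seed 1 --out-prefix work/toy

# split it into 10 kb pieces with a ground-truth AGP
scafeval splitref --genome work/toy.genome.fasta --piece-size 10kb \
    --out-prefix work/toy

# simulate an imperfect scaffolder: 5 rearrangement operations
scafeval perturb --truth-agp work/toy.truth.agp -k 5 --seed 2 \
    --contigs work/toy.pieces.fasta --out-prefix work/run1

# score it (TSV + JSON report, baseline row included)
scafeval score --reference-agp work/toy.truth.agp \
    --scaffold-agp work/run1.agp --method run1 --out-prefix work/run1.report

# downsample a Hi-C pair table to 100 pairs/kb
scafeval downsample --pairs work/pairs.tsv --assembly-length 500000 \
    --density 100 --seed 3 --out work/pairs.100.tsv

# rank methods across conditions
scafeval compare work/run1.report.tsv work/run2.report.tsv
```

For real scaffolder output, score either from its AGP
(`--scaffold-agp`), or from its FASTA via exact contig substring
matching (`--scaffold-fasta` + `--contigs`). The truth layout can come
from a known AGP, or be inferred from contig-to-reference alignments
(`--coords` for MUMmer `show-coords` output, `--paf` for PAF): each
contig is assigned to the chromosome holding most of its aligned bases,
positioned at the aligned-length-weighted midpoint, and oriented by
majority strand. Contigs below `--min-aligned-fraction` (default 0.5)
are left unplaced; `--exclude-unscaffolded` drops contigs the scaffolder
did not place instead of scoring them as singletons.

## Acceptance checks

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the binding correctness checks from scratch: DCJ distance versus
a brute-force breadth-first-search oracle (exhaustive for ≤ 3 contigs,
500 random 4–5-contig layouts), perfect-reconstruction identities,
perturbation distance bounds and dose–response monotonicity, hand-derived
worked metric values, file round trips, downsampling exactness, baseline
behavior and metric invariants. It prints a per-criterion summary to
stderr and exits non-zero on any failure. There are no dataset-level
numeric targets (those would require external genomes, Hi-C archives and
third-party scaffolder binaries), so the emitted JSON target map is
empty by design.

## Conventions

* Internal coordinates are 0-based half-open; `show-coords` and AGP are
  converted at the I/O boundary, PAF passes through.
* All chromosomes/scaffolds are treated as linear. A contig's head is
  its 3′ end in forward orientation.
* Gaps carry no metric weight; they are preserved only in AGP I/O.
* Layouts being compared must agree on contig lengths; contigs present
  in only one layout are excluded (and counted) before scoring.
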