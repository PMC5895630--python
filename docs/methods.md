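# Methods

## Generative model of the screen

The simulator reduces the wet workflow to three scalar parameters per
library member *i* and one shared rate:

* **input abundance** a_i ≥ 0, Σ a_i = 1 — the member's proportion in the
  pooled library (pooling is never perfectly equimolar; defaults draw a_i
  lognormal with σ = 0.25 around equimolar);
* **efficiency** e_i ≥ 0 — the member's relative propensity to be de novo
  ubiquitylated, with all wt controls sharing the reference e_wt = 1;
* **background** b ≥ 0 (default 0.01·e_wt) — a shared additive rate for
  nonspecific pull-down. The wet protocol blocks bead surfaces with excess
  unbarcoded nucleosomes precisely because some material is captured
  regardless of ubiquitylation state; the protocol motivates but does not
  quantify this term, so it enters as a single small additive constant.

The input sample draws `read_depth` fragments multinomially with weights
a_i; each IP replicate draws with weights a_i·(e_i + b). Every fragment
emits a nucleosomal-barcode read and a multiplexing-barcode read. A fraction
`decoy_fraction` (default 0.05) of fragments is replaced by uniformly random
sequence: this stands in for a PhiX spike-in, whose only property relevant
to the analysis is that it matches no barcode. I.i.d. substitution errors
(default 0.5% per base; no indels — the reads are short and matching is
substitution-based) are applied to every read. Quality strings are constant
Q30 placeholders; no stage consumes qualities.

Under this model the exact expectation of the pipeline readout is

  E[log2FC_i] = log₂((e_i + b) / (e_wt + b)),

which is what the truth tables record and what recovery statistics are
scored against.

**What the generator does not emulate:** enzyme kinetics, PCR amplification
bias, bead-capture chemistry beyond the scalar (e_i, b) model, indel errors,
quality-score structure, or optical duplicates. Passing recovery tests
therefore demonstrates correctness of the analysis under multinomial
sampling with member-specific capture rates — not robustness to every
artifact of real sequencing.

## Default library composition

Only the counts fixed by the modeled screen's description are hard
defaults: 36 members bearing a lysine-acetylation mark spread over all four
core histones, six unmodified wt controls, and two negative controls whose
H2BK120 site is pre-occupied (K120ub, K120ac — the latter is itself one of
the 36 acetylations). The remaining default members (two H2A.Z variants,
one free-DNA species, H2BS112/123GlcNAc, H3Y41ph, a few methylations, 5mC)
are representative stand-ins: the true member-level composition of such
libraries is supplementary material not reproduced here, and every count is
configurable through `CompositionConfig`.

Ground-truth efficiencies are drawn with log₂ effects inside [−3, 2],
structured by modification class to mirror the reported biology (H2A-tail
K13/K15 acetylation and H2A.Z strongly inhibitory; K5/K9 mildly so;
H3Y41ph and H2BS112GlcNAc stimulatory; most other marks near-neutral);
negative controls and free DNA get e = 0.05·e_wt.

## Barcode design and matching

Barcodes are random k-mers (default k = 8) accepted greedily under an
all-pairs Hamming-distance constraint (default ≥ 3). Requests beyond the
Singleton bound 4^(k−d+1), or that the sampler cannot satisfy within its
attempt budget, raise a capacity error. Multiplexing barcodes (default
length 6, distance ≥ 3) are designed the same way.

Matching is exact by default on both barcode classes — the modeled
workflow's scripts state no mismatch policy, and exact matching is the
conservative reading. With `max_mismatch > 0` a read is assigned only to a
*unique* nearest barcode within the tolerance; ties are unassigned. Because
default barcodes sit at pairwise distance ≥ 3, tolerance 1 can never create
ties, which is why member counts are monotone in the tolerance there. The
nucleosomal barcode is matched at a fixed configured offset (default 0)
rather than by scanning; the multiplexing barcode is matched as a read
prefix. Unassigned reads are tallied per class and logged, never silently
dropped.

## Normalization conventions

* Pseudocount α = 0.5 is added symmetrically to every raw count before
  forming proportions: it keeps ratios finite in the presence of zero
  counts while perturbing high-count members negligibly (α = 0 is allowed
  and raises a domain error on zero input counts).
* The wt-control average is **arithmetic on the ratio scale** (reading
  "average signal" literally); the geometric mean is available via
  `control_scale="geometric"` since the averaging scale is a genuine
  convention choice. With the arithmetic mean, the mean of normalized wt
  ratios is exactly 1 in every replicate — asserted to machine precision.
* One shared input sample per run (per-replicate inputs are supported by
  passing a sheet with one input per replicate group and calling the
  normalization functions directly).
* SEM uses the n−1 sample SD over √n; it is NaN for n = 1 and exactly 0
  when all replicates are bit-identical (the mean-subtraction rounding
  residue is suppressed in that case so z-scores behave).
* Ranks are 1..M by descending mean log2FC, ties broken lexicographically
  by member id, making outputs permutation-equivariant and deterministic.
* Hit labels (default |log2FC| ≥ 0.5 and |mean|/SEM ≥ 2; wt controls always
  neutral) are a reporting convention, flagged as such in output metadata —
  no multiple-testing machinery or count-dispersion modeling is attempted,
  matching the mean ± SEM reporting style of the screens modeled.

## Metaprofiles

Coordinates are 0-based half-open throughout; the TSS of a minus-strand
gene is `end − 1`. Fragment-length bounds are inclusive on both sides
("spanning 100–200 bp" read as a closed interval). Bin values are means of
per-base coverage (default bin 25 bp, the binning of the ubiquitylation
ChIP dataset modeled); bases beyond chromosome edges contribute 0, not NA,
with a logged warning. Scale-regions maps body base j of an L-bp gene to
bin ⌊j·B/L⌋; genes shorter than B bases are skipped and counted. All
matrices are oriented 5′→3′ so column 0 is the 5′-most bin for both
strands; this makes the strand-involution property (mirror the track, flip
the strand, recover the matrix) exact. When a gene annotation carries a
biotype column, only protein-coding entries are used by default. Window
widths and row sorting for heatmaps are configurable and recorded in output
headers, as the corresponding published parameters are not fully specified.

## Synthetic genomes

Default genome: two chromosomes totaling 1 Mb with ~100 non-overlapping
genes (2–10 kb) on both strands, kept ≥ 2.5 kb from ends and from each
other so flanking windows do not collide; the generator caps genomes at
5 Mb. Mark templates are deterministic functions of the transcription
coordinate (Gaussian TSS peak, σ = 80 bp, emulating promoter-proximal
variant nucleosomes; a gene-body ramp-plateau-decay emulating
elongation-coupled marks; boxcar and flat primitives for exact unit tests),
with optional additive Gaussian noise clipped at 0. Fragments have
truncated-normal lengths (147 ± 30 bp, resampled into [80, 250]) and
uniform placement. At noise 0 all outputs are exact template copies, which
is what makes the shape-recovery check deterministic.

## Determinism and problem sizes

A single run seed governs every stochastic stage through
`blake2b(f"{seed}:{stage}") mod 2³¹`, so identical configs give
byte-identical FASTQ/TSV/bedGraph outputs and any stage can be rerun in
isolation. Validation experiments use the screen's stated conditions —
3 replicates at 5×10⁵ reads per sample over five seeds for recovery;
replicate counts {3, 12, 48} at 2×10⁴ reads for SEM scaling (the scaling
law is depth-free, so the smaller depth just keeps the experiment quick).
SEMs are pooled across members on the squared scale (RMS): sem² is the
unbiased estimator of σ²/n, whereas the raw sample SD is biased low at
small n (c₄(3) ≈ 0.886), which would distort the 1/√n comparison by
construction.

## Known limitations

* The counter holds one chunk of reads (default 5×10⁵) in memory and the
  dense coverage representation holds whole chromosomes; both are sized for
  screen-scale and desk-scale genomic data, not for mammalian-genome BAMs.
* bedGraph is the only coverage input format (no bigWig), and read mapping
  / trimming are out of scope — the metaprofile stage consumes
  already-positioned fragments and tracks.
* Real-data mode is limited to the file formats above; the published
  datasets the screen analysis was originally applied to are not fetched or
  reproduced here.
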