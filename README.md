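# clipsplice

Toolkit for analysing how a spliceosomal RNA-binding protein's contacts
and downstream splicing outcomes differ between conditions, from
iCLIP-style sequencing and junction-count data:

- **Crosslink-site calling** — truncation tags at the nucleotide
  immediately 5' of each read start, deletion tags from CIGAR D
  operations, per-nucleotide snRNA binding profiles, deletion-fraction
  estimates at candidate crosslinked nucleotides, and windowed
  "proportion of total hits" region summaries.
- **Maximum-entropy splice-site strength** — retrainable maxent5/maxent3
  models over donor 9-mers and acceptor 23-mers with
  weak (< 3) / intermediate / strong (> 8) stratification and a biphasic
  score-distribution diagnostic.
- **Differential binding** — CPM normalisation, pseudocounted log2 fold
  changes with the |log2FC| > 1 selection, excess-kurtosis summaries of
  fold-change distributions, and exact/sampled label-permutation tests
  for windowed region enrichment.
- **Splicing events** — percent-spliced-in (PSI) from junction counts,
  per-event F tests and a global t test on PSI variability, differential
  event calling (binomial LRT, BH, p_adj < 0.05 and |ΔPSI| > 0.05), and
  annotated-vs-cryptic junction classification.
- **Synthetic data** — generators for every input above with recorded
  ground truth, so the whole pipeline is testable end-to-end with no
  external downloads.

It is aimed at analysts who want the statistical machinery of these
analyses as an importable, tested library (plus a thin `clipsplice` CLI)
rather than as one-off scripts.

## The statistics at the core

A maxent splice-site model is the maximum-entropy distribution p over
windows x subject to matching the training marginals on a constraint
family C (singles + adjacent pairs by default): fitted by iterative
proportional fitting over the enumerated 4^9 donor space, or by the exact
Markov-chain factorisation for 23-mer acceptors. A window scores

    maxent(x) = log2 p_signal(x) − log2 p_background(x)

The deletion-fraction estimator at position j is
deletions(j)/coverage(j) per sample, averaged unweighted across samples.
PSI per sample is mean(inclusion counts)/(mean(inclusion) + skipping).
Details, assumptions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate one iCLIP sample (50,000 reads on a 106-nt U6-like reference,
deletion probability 0.043 at 1-based positions 64–65), call crosslinks
and recover both the crosslinked nucleotide and a region proportion:

```python
import numpy as np
from clipsplice import synthetic_data as sd, crosslink as cl, maxent

rng = np.random.default_rng(64)
seq = "".join(rng.choice(list("ACGT"), size=106))
profile = np.ones(106)
profile[40:48] += 30.0   # ACAGA-box-like peak
profile[58:66] += 15.0   # stem-loop peak
profile[-1] = 0.0
truth = sd.SimulationTruth(
    seed=1, references=[("U6", seq)],
    binding_profile={"U6": profile / profile.sum()},
    deletion_sites={"U6": [63, 64]}, deletion_prob=0.043,
    read_length=30, n_reads_per_sample=50_000,
    samples=[("rep1", "RP13"), ("rep2", "RP13")],
)
clip = sd.simulate_clip_reads(truth, "run/")
lib = cl.load_sam(clip.sam_paths["rep1"])
calls = cl.call_crosslinks(lib.reads, lib.reference_lengths, "rep1")
prof = cl.build_profile(calls.tags, "rep1", "U6", 106)
site = cl.deletion_fraction(lib.reads, "U6", 64)
region = cl.region_proportion(prof, (25, 47))
print(f"truncation tags: {prof.total_tags()}")
print(f"deletion fraction at 1-based 65: {site.deletion_fraction:.4f} (coverage {site.coverage})")
print(f"proportion of hits in window 25-47: {region.proportion_of_total_hits:.4f}")
```

prints

```
truncation tags: 50000
deletion fraction at 1-based 65: 0.0425 (coverage 38640)
proportion of hits in window 25-47: 0.5002
```

— the estimator recovers the planted 4.3% deletion probability within
binomial sampling error, and the window proportion reflects the share of
binding placed there by the profile. Scoring splice-site windows:

```python
sig, dec = sd.simulate_splice_site_sets(
    [0.5, 0.5, 1.0, 2.0, 2.0, 1.2, 1.0, 0.8, 0.5],
    n_signal=800, n_decoy=800, seed=9, consensus="CAGGTAAGT",
)
model = maxent.fit_maxent(sig)
for s in maxent.score_batch(model, [sig[0], dec[0]]):
    print(f"{s.sequence}  maxent5 = {s.score:+.2f}  ({s.category})")
```

```
CAGGTAAGT  maxent5 = +14.80  (strong)
CTAAACGCA  maxent5 = -11.65  (weak)
```

The same stages are scriptable from a shell:

```bash
clipsplice simulate --seed 7 --out-dir run/
clipsplice clip-call run/clip/*.sam --out-dir run/calls/
clipsplice splice-events run/junction_counts.tsv \
    --case case --control control --out run/calls/events.tsv
clipsplice report run/calls/ --out run/report.md
```

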