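# promarch

Promoter-architecture analysis for metazoan genomes: tell apart
**developmental** core promoters — TATA-box / DPE / INR motifs, focused
transcription initiation at a single dominant TSS — from **housekeeping**
core promoters — TCT / DRE / Ohler1/6 motifs, dispersed initiation across
50–100 bp aligned to a well-positioned +1 nucleosome — and measure how each
class responds when a general transcription factor is depleted.

It is written for regulatory-genomics analysts who have per-base 5′-end
tracks (CAGE or reporter-initiation assays), MNase fragments, and
nascent-transcription count tables with spike-in tallies, and who want the
whole chain from raw positions to per-promoter classes and calls as a
reusable, deterministic library rather than a pile of one-off scripts.

## What it computes

* **CAGE-based TSS correction** — annotated TSSs move to the strongest
  same-strand CAGE position within ±250 bp (primary track first, then
  fallbacks in order), retried at ±500 bp, else kept; one transcript per
  unique TSS (the longest).
* **Positional PWM classification** — per-motif percent-of-optimum scores
  `100·(S* − S_min)/(S_max − S_min)` in TSS-relative search windows;
  strict presence thresholds (TATA > 90%, INR > 95%, DPE > 98%, TCT > 95%,
  Ohler1 > 95%, Ohler6 > 97%, Ohler7 > 95%, DRE > 98%); exclusive labels
  with precedence TCT > TATA > DPE > INR > DRE > Ohler1/6; a k-means
  (k = 9) overview; stringent prototype-selection rules with a ≥ 5 tpm
  activity filter.
* **Initiation-shape metrics** — dominant TSS, dominant fraction, number
  of activated TSSs (> 20% or ≥ 20% of the dominant count), initiation
  width, −1/+1 dinucleotides, and motif- or nucleosome-anchored
  metaprofiles with a single-motif-occurrence filter.
* **+1 nucleosome alignment** — nucleosome centers from 100–200 bp MNase
  fragment centers (max coverage in +1..+200 bp of the dominant TSS) and
  the per-promoter CAGE×MNase Pearson cross-correlation over lags
  −50..+200; housekeeping promoters peak near lag +125.
* **Spike-in–normalized depletion response** — size factors from
  spike/reference read ratios (geometric mean 1), an exact conditional
  binomial test on replicate-summed counts, BH FDR, down-calls at
  fold change > 1.5 and FDR < 0.05, Fisher motif enrichment of the
  down-set, ChIP z-scores by promoter class, and candidate-intermediary
  set intersections.
* **A seeded synthetic-data generator** producing genomes, transcript
  models, CAGE/MNase/count data with exactly the structure above, plus
  full ground truth — the substrate for every recovery test.

## Worked example

```python
import numpy as np
from promarch import SimConfig, DepletionScenario
from promarch.synthetic import (simulate_promoter_landscape, simulate_cage,
                                simulate_mnase, simulate_depletion_counts)
from promarch.classify import (PromoterAnchor, score_promoters,
                               apply_thresholds, assign_class)
from promarch.pwm import default_pwms, default_windows
from promarch.initiation import extract_profile, profile_metrics
from promarch.chromatin import fragment_center_track, plus1_center
from promarch.depletion import spike_size_factors, call_downregulated

cfg = SimConfig(n_per_class=50, seed=1,
                scenario=DepletionScenario(
                    target_classes=("TATA", "DPE", "INR"), fold_change=0.25))
genome, transcripts, truth = simulate_promoter_landscape(cfg)
cage = simulate_cage(truth, cfg)

anchors = [PromoterAnchor(r["promoter_id"], r["contig"], r["tss"], r["strand"])
           for _, r in truth.promoters.iterrows()]
scores = score_promoters(genome, anchors, default_pwms(), default_windows())
labels = assign_class(apply_thresholds(scores["percent"]))
acc = (labels == truth.promoters.set_index("promoter_id")["class_label"]).mean()
print(f"class recovery: {acc:.1%} of {len(labels)} promoters")

fracs = {"focused": [], "dispersed": []}
for _, r in truth.promoters.iterrows():
    prof = extract_profile(cage, r["promoter_id"], r["contig"],
                           r["tss"], r["strand"], 120, 120)
    group = ("focused" if r["class_label"] in ("TATA", "DPE", "INR")
             else "dispersed")
    fracs[group].append(profile_metrics(prof).dominant_fraction)
print(f"median dominant fraction: focused {np.median(fracs['focused']):.2f}, "
      f"dispersed {np.median(fracs['dispersed']):.2f}")

track = fragment_center_track(simulate_mnase(truth, cfg))
hk = truth.promoters[truth.promoters["class_label"] == "DRE"]
offs = [plus1_center(track, r["promoter_id"], r["contig"], r["tss"],
                     r["strand"]).center_offset for _, r in hk.iterrows()]
print(f"median +1 nucleosome offset (DRE promoters): +{int(np.median(offs))} bp")

cm, count_truth = simulate_depletion_counts(cfg, truth)
factors = spike_size_factors(cm.samples["spike_reads"],
                             cm.samples["reference_reads"])
de = call_downregulated(cm, factors)
true_down = count_truth.genes["fold_change"] < 1
called = de["down"]
print(f"depletion calls: {int(called.sum())} genes down "
      f"(sensitivity {(called & true_down).sum() / true_down.sum():.1%}, "
      f"{int((called & ~true_down).sum())} false positives)")
```

Output:

```
class recovery: 96.7% of 300 promoters
median dominant fraction: focused 0.80, dispersed 0.15
median +1 nucleosome offset (DRE promoters): +124 bp
depletion calls: 150 genes down (sensitivity 100.0%, 0 false positives)
```

Reading it: motif classes are recovered from sequence alone for ~97% of
promoters; focused promoters put 80% of initiation on one base while
dispersed promoters put 15%; the +1 nucleosome of housekeeping promoters
is found ~125 bp downstream of the dominant TSS; and with spike-in size
factors, exactly the 150 developmental-promoter genes given a true 4-fold
depletion are called down, with no false positives.

The same flow is available from the shell:

```sh
promarch all --seed 1 --out run/          # simulate into run/data, analyze into run/report
promarch analyze --data run/data --out run/report
promarch correct-tss --transcripts t.bed --cage cage --out out/
```

`run/report/` then holds TSV tables (classification, initiation metrics,
nucleosome calls, cross-correlation curves, differential calls, motif
enrichment), each stamped with the config hash, plus a SHA-256 manifest —
two runs with the same seed are bit-identical.

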