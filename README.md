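# dosechrom

Quantitative modeling of how regulatory-element (RE) chromatin accessibility
responds to transcription-factor (TF) dosage.

When a dosage-sensitive TF (e.g. TWIST1 or SOX9 in facial progenitor cells)
is titrated down with a degradation-tag system, ATAC-seq accessibility at its
target REs falls along curves that range from *buffered* (little change until
the TF is nearly gone) to *sensitive* (proportional loss from the first
dosage decrement). `dosechrom` implements the quantitative machinery for
analyzing such titrations, for computational biologists working on
cis-regulatory logic and TF dosage sensitivity:

1. **Dose-response fitting** (`dosechrom.dose_response`) — TMM-normalized
   CPM, per-RE batch correction, and least-squares Hill fits
   `f(d) = min + (max−min)·d^h/(d^h+e^h)` with anchored asymptotes (a
   three-parameter variant with free maximum is used when it improves AIC by
   more than 2). Sensitivity is summarized by a **modified ED50**: the dosage
   at which the fitted curve reaches 50% of its value at 100% dosage, which
   caps the estimate at 100% and stabilizes it for very sensitive REs.
2. **TF–nucleosome competition model** (`dosechrom.nmc`) — the
   nucleosome-mediated cooperativity partition function

   ```
   Acc = Z_open / (Z_open + Z_nuc)
   Z_open = ∏_i (1 + α/K_D,i),   Z_nuc = L·∏_i (1 + c·α/K_D,i)
   ```

   with `L` the nucleosome/open equilibrium constant (default 10³) and
   `c ∈ [0,1]` the suppression of TF binding on nucleosomal DNA. The module
   computes forward accessibility curves, theoretical ED50s over an α
   titration (10⁻⁵–10⁵), the crossover K_D ratio at which a second (weaker)
   binding site stops buffering and starts sensitizing, and least-squares
   fits of `(c, a₁₀₀, K_D ratio)` to normalized empirical curves (fits with
   mse > 0.001 or c < 0 are rejected).
3. **CWM motif-instance analysis** (`dosechrom.motifs`) — contribution
   weight matrix (CWM) instance calling from per-base attribution tracks via
   continuous Jaccard similarity with permissive percentile thresholds
   (Jaccard ≥ 10th percentile, total |contribution| ≥ 0.5th percentile of a
   high-attribution reference), exact p-value-thresholded PWM matching
   (dynamic programming over 0.01-bit score bins), summit-distance and
   conservation contrasts against a shuffled control.
4. **Synthetic study designs** (`dosechrom.simulate`) — generators that
   emulate the experimental design (five dosages × four replicates × two
   batches, negative-binomial counts; contribution tracks with planted
   buffering/sensitizing motifs; model-generated response curves), with
   exact ground truth so every stage is benchmarked end to end.

## Worked example

```python
import numpy as np
from dosechrom.nmc import NMCParams, SiteSet, crossover_ratio, theoretical_ed50

params = NMCParams(L=1e3, c=0.01)          # strong TF-nucleosome competition
one = theoretical_ed50(SiteSet.explicit([1.0]), params)
two = theoretical_ed50(SiteSet.explicit([1.0, 1.0]), params)
weak = theoretical_ed50(SiteSet.explicit([1.0, 10.0]), params)
print(f"{one:.1f} {two:.1f} {weak:.1f}")   # 90.8 39.2 149.0
print(f"{crossover_ratio(params):.2f}")    # 4.60
```

A single high-affinity site half-saturates at α ≈ 90.8. Adding a second
*identical* site buffers the response (ED50 drops to 39.2 — the two sites
cooperate through the shared nucleosome), but adding a 10-fold *weaker* site
sensitizes it (ED50 rises to 149.0). The crossover between the two regimes
sits at a K_D ratio of ≈ 4.6; with weak competition (`c=0.001`) it moves to
≈ 247, and with `c=0` it disappears — any second site buffers.

The numbered drivers under `analysis/` run the full study on synthetic data
(each regenerates its inputs deterministically and writes tables under
`results/`):

```bash
python analysis/01_simulate_study.py    # synthetic counts, tracks, curves
python analysis/02_fit_dose_response.py # Hill fits + ED50 recovery
python analysis/03_nmc_theory.py        # ED50 vs K_D ratio, crossovers
python analysis/04_fit_nmc.py           # n-scan + competition-model fits
python analysis/05_motif_analysis.py    # instance calling + class contrasts
```

For example, `04_fit_nmc.py` prints the effective-site-number scan and the
per-model medians:

```
n-scan median mse minimized near nHA=3 (selected)
nHA=3: 200/200 accepted, median c=0.02178
nHA=3,nLA=1: 50/50 accepted, median c=0.05839, median K_D ratio=15.7
```

and `05_motif_analysis.py` recovers the planted motif architecture
(precision/recall 0.99) with sensitizing instances farther from the summit
(median 82 bp vs 20 bp) and far less PWM-detectable (64% vs 98%).

A `dosechrom` CLI wraps the same library
(`dosechrom simulate|fit-hill|nmc-fit|nmc-crossover|call-instances|conservation-contrast|run`);
`dosechrom run --config cfg.yaml` executes the whole pipeline with a
manifest of artifact hashes, byte-reproducible from the config and seed.

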