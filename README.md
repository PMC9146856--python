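# cequal

Frame-quality analysis for small-bowel capsule endoscopy (CE).

Bubbles, debris and bile can mask the mucosa in a capsule recording and
lower its diagnostic value, and human cleanliness scores are poorly
reproducible. `cequal` implements a fully computational alternative and the
statistics needed to compare two bowel-preparation regimens with it:

* **Bubble abundance.** Each frame's circular field of view is quantised to
  32 grey levels and a grey-level co-occurrence matrix (GLCM) `p(i, j)` is
  accumulated over pixel pairs at distance 1 in four orientations. The
  Haralick contrast `C = Σᵢⱼ (i − j)² p(i, j)` spikes on the bright annular
  texture of bubbles; a frame is *abundant in bubbles* (bubbles on ≥ 10% of
  the visible surface) when `C ≥ τ`, with τ calibrated by maximising the
  Youden index on labelled synthetic frames.
* **Cleanliness.** The R/G score — mean red over mean green intensity in the
  field of view. Mucosa is red, debris and bile are green; a frame is
  *adequately cleansed* when R/G > 1.6 (strict).
* **Aggregation and statistics.** Scores are pooled per quartile (Q1–Q4) of
  each small-bowel sequence and compared between preparation arms
  (`SMT−` without and `SMT+` with the anti-foaming agent simethicone) with a
  two-way mixed repeated-measures ANOVA, plus Welch t-tests, Pearson
  chi-square tests, screening-flow filters, and the study report tables
  (diagnostic yield, transit times, completion rate).

Because no public annotated CE recordings exist, the package ships a
synthetic generator (`cequal.synthetic`) that renders endoscope-like frames
with *planted* ground truth — controlled bubble coverage, controlled R/G
balance, per-quartile rates, findings and completion metadata — so the whole
pipeline is testable end to end and recovers what was planted. It is aimed
at researchers prototyping CE image-quality scores and at anyone who needs a
reference implementation of masked GLCM texture features or the split-plot
ANOVA workflow.

## Worked example

```python
from cequal import FrameSpec, render_frame, score_frame, calibrate

cal = calibrate(seed=1, n=500)
print(f"tau = {cal.tau:.2f}  (sensitivity {cal.sensitivity:.3f}, specificity {cal.specificity:.3f})")

frame = render_frame(FrameSpec(true_bubble_coverage=0.18, rg_balance=1.9, seed=42))
s = score_frame(frame, tau=cal.tau)
print(f"contrast = {s.contrast:.2f} -> {s.bubble_class}")
print(f"R/G      = {s.rg_ratio:.3f} -> {s.cleanliness_class}")
```

prints

```
tau = 11.62  (sensitivity 0.985, specificity 0.971)
contrast = 19.63 -> abundant
R/G      = 1.903 -> adequate
```

The threshold calibrated on 500 labelled frames separates the two classes
with ~97–98% sensitivity/specificity; the example frame, rendered with 18%
bubble coverage and R/G balance 1.9, is correctly classified abundant in
bubbles (≥ 10%) and adequately cleansed (> 1.6).

The same flow is available from the shell:

```sh
cequal simulate --seed 1 --out run/           # PNG frames + sidecars + roster
cequal score    --in run/ --out run/scores/   # per-frame and per-video CSVs
cequal report   --scores run/scores/ --roster run/roster.csv --out run/report/
cequal screen   --out flow.json               # screening flow-chart counts
```

## Layout

| module                  | contents                                                     |
| ----------------------- | ------------------------------------------------------------ |
| `cequal.frame`          | frame container, circular field-of-view geometry, PNG I/O    |
| `cequal.synthetic`      | frame/video/cohort/roster generators with planted truth      |
| `cequal.frame_scoring`  | masked GLCM, contrast, τ calibration, R/G score              |
| `cequal.video`          | quartile splitting, per-video summaries, reader outcomes     |
| `cequal.stats`          | mixed repeated-measures ANOVA, t/chi-square, report tables   |
| `cequal.screening`      | inclusion/exclusion filters and flow-chart counts            |
| `cequal.pipeline`       | calibrate → simulate → score → aggregate → report            |
| `cequal.cli`, `cequal.io` | `cequal` command-line tool and disk formats                |

See `docs/methods.md` for the model, the generator's assumptions and the
numerical choices.
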