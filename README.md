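# scanpath3d

Gaze-pattern analysis for viewers walking around free-standing
sculptures.  Mobile eye-tracking studies of three-dimensional artworks
map every fixation onto one of eight reference photographs taken at 45°
steps around the sculpture; `scanpath3d` implements the full analysis
chain that such data support, for researchers comparing viewers with
different levels of domain expertise:

* **Global/local viewing** — each fixation is labelled *global*
  (ambient, broad exploration) or *local* (focal, detailed inspection)
  by a duration threshold (default 187 ms; a fixation is local iff its
  duration strictly exceeds it).  Per participant the package reports
  the global/local count ratio and the switching frequency
  (label transitions per second of inspection time).
* **Scanpath distance** — a double-mapping nearest-neighbour distance
  between two participants' fixation sequences.  Each fixation is a 3-D
  point (x, y, scaled duration); durations are scaled by a per-sculpture
  conversion factor *c = sculpture height in px / longest fixation in
  ms* so the duration axis spans the same range as the y axis.  For
  point sets *S* and *T*,

      D(S, T) = [ Σ_{p∈S} min_{q∈T} d(p,q) + Σ_{q∈T} min_{p∈S} d(p,q) ] / max(|S|, |T|)

  with *d* the Euclidean distance.  D is evaluated per reference image
  and averaged over the images both participants fixated.  Pairwise
  distances are pooled by **expertise divergence** — the absolute
  difference of the two viewers' expertise levels (layperson = 0,
  novice = 1, semi-expert = 2, expert = 3, classified from years of
  experience: 0 / <5 / 5–10 / >10).
* **Basic-feature (AOI) metrics** — expert-defined polygonal areas of
  interest keep one identity across all eight perspectives; the package
  reports distinct features fixated, the percentage of fixations on
  features, and revisits per minute (a revisit = re-entry into a
  feature after at least one fixation outside it; dwelling is not a
  revisit).
* **Synthetic cohorts** — a generator emulating the study design (4
  expertise groups × 5 participants × 2 sculptures × 8 perspectives)
  with a two-state global/local Markov chain, lognormal duration
  mixture, AOI attraction and per-group gaze-centre offsets, so the
  whole pipeline is testable without the original museum recordings.

## Worked example

```python
import scanpath3d as s3d

cfg = s3d.default_config(seed=42)            # 4 levels x 5 participants
cohort = s3d.generate_cohort(cfg)
profiles = cohort.profiles()

paths = cohort.scanpaths("moses")
factor = s3d.compute_conversion_factor(paths, sculpture_height_px=600)
matrix = s3d.pairwise_matrix(paths, profiles, factor)
print(s3d.divergence_summary(matrix)[["divergence", "n", "mean"]])
```

```
   divergence   n        mean
0           0  40  119.602237
1           1  75  132.950969
2           2  50  165.011775
3           3  25  217.235711
```

40/75/50/25 pairs fall at divergence 0–3 (the combinatorics of four
groups of five), and the mean double-mapping distance rises with
divergence — the generator places each level's gaze centre 60 px
further along the image, and the distance recovers that ordering.  The
computed conversion factor here is 0.491 px/ms (600 px sculpture
height / 1222 ms longest fixation).

The same analyses run as numbered drivers over a shared synthetic
cohort:

```sh
cd analysis
python 01_simulate_cohort.py      # writes results/data/
python 02_global_local.py         # ratio + switching by level
python 03_scanpath_distances.py   # pairwise matrices + divergence summary
python 04_aoi_metrics.py          # coverage, %, revisits/min by level
python 05_published_table_arithmetic.py
```

or through the CLI (`scanpath3d simulate / globallocal / eyenalysis /
aoi / run`), e.g.

```sh
scanpath3d simulate --seed 42 --out data
scanpath3d run --fixations data/fixations.csv --meta data/meta.csv \
    --aois data/aois_moses.yaml --aois data/aois_daphne.yaml \
    --height-px moses=600,daphne=1050 --out results
```

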