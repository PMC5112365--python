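# threaddrift

Topic-drift and counteraction analysis for threaded online discussions,
built for moderated consumer-health forums where a thread that wanders
away from its original question can leave the original poster without an
answer.

`threaddrift` answers three questions about a threaded corpus:

1. **How far has each reply drifted from the thread's opening post?**
   Every post is a sparse tf-idf vector (tf = raw within-post count,
   idf = ln(N/df) computed per community over all posts); drift is the
   cosine similarity between a reply and the original post,
   cos(u, v) = u·v / (‖u‖‖v‖) ∈ [0, 1].
2. **Is a given reply off topic?** The corpus-wide mean similarity at
   each thread position (kept only where ≥ `min_support` posts
   contribute) forms a positional baseline; a reply is classified as
   drift when its score falls strictly below the baseline at its own
   position. The baseline's decline is summarized with a logarithmic
   trend y = a·ln(position) + b.
3. **Who pulls threads back on topic?** A *counteraction* is an
   irregular increase of similarity-to-first-post relative to the
   preceding reply. Counteractions are credited to the posting member,
   normalized by the member's reply count in the thread
   ("counteraction effort"), aggregated by mutually exclusive
   per-thread roles (staff/MD moderator, original poster, power user,
   regular user), and compared with a Kruskal–Wallis H test plus
   pairwise Mann–Whitney U tests (Holm–Bonferroni corrected, with
   rank-biserial effect sizes r = 1 − 2U/(n₁n₂)).

A lexicon module flags posts where members themselves name the drift
("hijacked", "off topic") and threads announced as off topic via an
"OT" title, and an evaluation module provides the confusion-matrix
arithmetic (precision, recall, accuracy, F1) used to score the
detectors. Because real forum scrapes are rarely redistributable, the
package ships a seeded synthetic-corpus generator with per-post ground
truth, so the whole pipeline is testable end to end.

## Worked example

```python
from threaddrift import (
    SynthConfig, generate_corpus, corpus_stats, filter_threads,
    corpus_trajectories, position_baseline, fit_log_trend,
    evaluate_drift_detection, evaluate_counteraction_detection, role_effort_study,
)

cfg = SynthConfig(n_threads=200, seed=7)        # one synthetic community
corpus, gold = generate_corpus(cfg)

stats = corpus_stats(filter_threads(corpus))
model, trajectories = corpus_trajectories(corpus)
baseline = position_baseline(trajectories, min_support=20)
trend = fit_log_trend(baseline)
cm, report = evaluate_drift_detection(corpus, gold, min_support=20)
```

printing the baseline, trend and scores gives:

```
threads=200 posts=1440 mean_TL=7.20 max_TL=37
position 2: mean sim_to_first = 0.686 (n=200)
position 3: mean sim_to_first = 0.658 (n=164)
position 4: mean sim_to_first = 0.605 (n=137)
position 5: mean sim_to_first = 0.617 (n=117)
log trend: slope=-0.0579 intercept=0.6926 R2=0.26
drift detection vs gold: F1=0.89 (precision=0.80, recall=1.00)
counteraction detection recall=1.00
original_poster  mean effort=0.07 (n=31)
power_user       mean effort=0.06 (n=24)
regular_user     mean effort=0.01 (n=72)
staff_md         mean effort=0.03 (n=12)
```

Reading the output: average similarity to the opening post declines
with position (the negative slope is the gradual-drift signature), the
positional-baseline classifier recovers the generator's abrupt-drift
labels with F1 0.89 at this small corpus size, and every generated
counteraction is detected as a similarity increase. Role efforts are
low in absolute terms here because, under the default conditions, a
reply can only counteract once its thread has noticeably drifted —
the ordering (original posters first) is the meaningful signal.

The same pipeline runs from the shell on any JSONL/CSV corpus in the
standard format (one post per line with community_id, thread_id,
position, author_id, role_tag, title, body, timestamp):

```bash
threaddrift simulate --out-dir run --seed 7
threaddrift stats --input run/corpus.jsonl --out-dir run
threaddrift detect-drift --input run/corpus.jsonl --out-dir run --min-support 20
threaddrift evaluate --input run/corpus.jsonl --labels run/labels.csv \
    --out-dir run --task drift --min-support 20
```

Every command writes its artifacts plus a manifest (config echo,
version, seed) so runs are reproducible.

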