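# alrexscan

Coding-region nucleotide features and motif analysis of 5′UTR-intron status
in genes encoding secretory and mitochondrial proteins.

## The problem

mRNAs of genes that encode secreted or mitochondrial proteins can leave the
nucleus through a splicing-independent export route (ALREX) driven by
nucleotide-level signals at the very start of the coding region — inside the
signal sequence coding region (SSCR) or the mitochondrial-targeting sequence
coding region (MSCR). Whether a transcript relies on this route correlates
with whether its 5′UTR carries an intron (a 5UI): genes *lacking* 5UIs keep
strong ALREX-associated sequence features, genes *carrying* 5UIs do not.

`alrexscan` is a reusable pipeline for quantifying that contrast. Given
coding sequences, a refGene-style annotation table (from which 5UI status
and 5′UTR length are derived) and leader-class gene lists, it computes:

- **codon composition** of the first 69 nt versus the rest of the ORF —
  adenine percentage, leucine:isoleucine and arginine:lysine usage, and the
  ratio of adenine-lacking to adenine-containing codons over the seven amino
  acids that have both kinds (L, V, A, P, S, G, R; analogously thymine over
  A, T, P, H, N, D, R, S, G) — with Wilcoxon rank-sum and pooled-count
  Fisher tests;
- **PSSM motif scanning** of the first 99 nt with log-odds (bits) scores,
  greedy overlap disambiguation, and a score threshold *t\** chosen to
  maximize the hypergeometric enrichment
  `P(overlap ≥ k | N, m, n) = Σᵢ C(m,i) C(N−m,n−i) / C(N,n)`
  of motif-containing sequences among 5UI⁻ genes;
- **Dirichlet random-PSSM nulls**: competitor motifs whose columns are
  independent Dirichlet draws with concentration equal to the background
  base frequencies (Σα = 1), ranked by ROC (TPR = fraction of 5UI⁻
  sequences called motif-containing, FPR = same for 5UI⁺) and a second
  threshold *t′* maximizing the TPR gap over the null median at matched FPR;
- **occurrence analyses**: presence and multi-copy fractions, translation
  frame distribution, and the 5′ positional bias of motif hits;
- **category enrichment** of 5UI status with log₁₀-odds (LOD) ranking and a
  Westfall–Young min-p resampling adjustment, plus a 5′UTR-length-stratified
  Cochran–Mantel–Haenszel control;
- a **synthetic-data generator** that plants all of these effects at
  configurable sizes, so every stage runs and is validated without any
  genome download.

## Worked example

```python
from alrexscan import (SyntheticConfig, gen_dataset, pssm_from_consensus,
                       select_threshold_tstar, rank_against_null)
from alrexscan.nullmodels import empirical_background
from alrexscan.pssm import max_window_score

cfg = SyntheticConfig(n_pos=500, n_neg=500, seed=1)   # 5UI- / 5UI+ groups
records, ledger = gen_dataset(cfg)
pos = [r.cds for r in records if not r.has_5ui]
neg = [r.cds for r in records if r.has_5ui]

bg = empirical_background(pos + neg)
motif = pssm_from_consensus("CGSSGC", background=bg)  # S = C or G
sel = select_threshold_tstar(
    [max_window_score(motif, s) for s in pos],
    [max_window_score(motif, s) for s in neg],
)
print(f"t* = {sel.t_star:.2f} bits, enrichment p = {sel.fisher_p:.3g}")

ranking = rank_against_null(motif, pos, neg, n_null=1000, seed=11)
print(f"min percentile vs 1000 random motifs: {ranking.min_percentile:.3f}")
```

prints

```
t* = 8.52 bits, enrichment p = 1.02e-16
min percentile vs 1000 random motifs: 0.992
```

meaning: the best threshold for the GC-rich consensus motif splits the two
groups with overwhelming enrichment among 5UI-lacking genes (237 of 500
5UI⁻ versus 113 of 500 5UI⁺ sequences called motif-containing), and across
the whole FPR range 0.1–0.7 the motif discriminates 5UI status better than
at least 99% of random motifs drawn from the background — the signature of
a genuine ALREX-associated element rather than a compositional artifact.

## Command-line pipeline

```bash
alrexscan run --outdir demo_run --seed 1          # all stages
alrexscan simulate --outdir demo_run --seed 1     # or stage by stage
alrexscan motif-scan --outdir demo_run --seed 1
alrexscan report --outdir demo_run
```

Stages (`simulate → ingest → redundancy → features → motif-scan →
null-rank → enrich`) write TSV/JSON reports plus a manifest with all seeds
and row counts; a fixed configuration reproduces byte-identical outputs.
Configuration can also be given as YAML via `--config`.

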