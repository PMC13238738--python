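# chromcall

Region-based chromatin enrichment calling: assign a present/absent
status — with an enrichment score, a z-score and an FDR-adjusted
p-value — to predefined fixed-width genomic windows (promoters,
enhancers, any user-supplied region set) from chromatin profiling
alignments (ChIP-seq, CUT&RUN, CUT&Tag, ATAC-seq).

Peak callers find high-signal loci with data-dependent boundaries, which
makes region-matched comparisons across marks and samples awkward.
`chromcall` instead tests a *fixed* region set: sequenced fragments are
reduced to their midpoints and counted per window, a genome-wide
Negative Binomial background is fitted once per experiment from
equal-width genome tiles (mean λ_g, global dispersion θ), and a matched
control locally modulates the expected background:

    m_i  = max(1, y_i(ctrl) / λ_g(ctrl))        λ_t,i = m_i · λ_g
    p_i  = P(Y ≥ y_i),  Y ~ NB(μ = λ_t,i, size = θ)     (Poisson as θ → ∞)
    s_i  = log2((y_i + ε) / (λ_t,i + ε))
    z_i  = (y_i − λ_t,i) / sqrt(λ_t,i + λ_t,i²/θ)

with Benjamini–Hochberg correction across regions; a mark is called
present when s_i > 1.5 and the adjusted p < 0.25. Calls for an active
and a repressive mark (e.g. H3K4me3 / H3K27me3) combine into four
chromatin states per region — N (neither), A (active), R (repressed),
B (bivalent) — and two samples over the same region set can be compared
through per-region delta metrics (Δscore, Δz, Δexpression). It is aimed
at anyone doing promoter- or enhancer-centric epigenomics: comparing
marks across treatments, time points or tumour pairs at consistent
coordinates.

## Worked example

`examples/01_call_promoter_status.py` simulates a toy genome in which 5
of 200 promoter windows carry an 8-fold enrichment over a background of
20 fragments per 2 kb window, then runs the full pipeline against the
matched control:

```
background: lambda_g = 22.11 fragments per 2000 bp tile over 400 tiles, theta = 2.16
presence calls: 5 of 200

    name   y  y_ctrl    m  lambda_t     padj  score    z  call
GENE0001 147      21 1.02      22.5  0.00109   2.66 7.77     1
GENE0002 153      21 1.02      22.5 0.000966   2.71 8.15     1
GENE0003 158      22 1.07      23.6 0.000966    2.7 8.03     1
GENE0004 166      19    1      22.1  0.00087   2.85 9.13     1
GENE0005 157      20    1      22.1 0.000947   2.77 8.56     1
```

Exactly the five spiked promoters are called: each shows ~7× its locally
adjusted expected count λ_t (≈22), a log2 enrichment score s ≈ 2.7 and a
tiny adjusted p-value, while the 195 null windows stay quiet. The other
examples cover chromatin-state integration (`02`), two-sample deltas
(`03`) and the synthetic-data generator (`04`).

The same pipeline is available from the shell:

```bash
chromcall simulate --spec spec.yaml -o fixtures/
chromcall call --treatment t.bam --control c.bam --regions regions.bed \
    --chrom-sizes g.sizes --width 2000 [--blacklist bl.bed] -o calls.tsv
chromcall states --active k4.tsv --repressive k27.tsv -o states.tsv
chromcall compare --sample-a recurrent.tsv --sample-b primary.tsv -o delta.tsv
```

`call` writes a TSV whose first three columns are BED-compatible plus a
`<output>.background.json` sidecar recording the fitted (λ_g, θ).

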