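# nucleoquant

Quantification pipelines for studying how a nucleolar-enriched protein (the
motivating case is the DNA-repair endonuclease APE1, endogenously
mEGFP-tagged in mouse embryonic stem cells) moves between nuclear
compartments under genotoxic and transcriptional stress, and how the purified
protein behaves in in vitro phase-separation assays.  The package is aimed at
cell biologists and microscopists who need reproducible, scriptable versions
of five common readouts:

1. **DNA-damage foci** (γH2AX / 53BP1): Laplacian-of-Gaussian spot detection
   on max projections — response `−LoG(I, σ=3)`, threshold `mean + 1.5·SD`
   over the image, 3×3 morphological opening, centroid-in-nucleus assignment.
2. **Nascent-RNA in fibrillar centres**: 3D segmentation of the nucleolar DFC
   (Otsu on fibrillarin within nuclei) and FCs (DoG-seeded watershed on UBF
   with a nucleoplasm-referenced seed filter), then the mean EU intensity per
   cell within FCs, normalized to a control group.
3. **Live-cell nucleolus/nucleoplasm ratio**: per-nucleolus ratio
   `mean(I_nucleolus) / mean(I_nucleoplasm)` tracked over a time-lapse, with
   a two-way repeated-measures (split-plot) ANOVA — time within subjects,
   treatment group between — and Tukey-HSD-adjusted per-frame contrasts to
   locate the earliest significant divergence.
4. **Droplet assays**: adaptive local-mean (Bradley) thresholding
   (`I ≥ 2(1−sensitivity)·μ_window`, sensitivity 0.4, window 99 px), speckle
   cleanup at 5 px, condensed fraction `Σ droplet area / image area`, and
   per-droplet partition ratios (mean inside / background mean), with probe
   ratios measured through the protein-channel mask.
5. **Biophysics utilities**: HSQC chemical-shift perturbation
   `Δδ = √(ΔδH² + (0.2·ΔδN)²)` with binding-residue flagging (volume loss
   > 2/3, shift above mean), copy-number → molar concentration, isoelectric
   point, and an exhaustive G-quadruplex motif scanner (four G-tracts of
   ≥ 2 G, window ≤ 20 nt) with per-region counts.

Every pipeline is exercisable without any external data through a bundled
synthetic-microscopy generator whose scenes carry closed-form ground truth
(`nucleoquant.synthetic`), including exponential nucleolar-depletion
time-lapses `r(t) = 1 + (r0−1)·e^{−(t−t0)/τ}` with exact per-frame
conservation of total nuclear signal.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Generate the reference focus-counting scene (50 nuclei, 5 foci each, spot
sigma 3 px, SNR 10), segment, detect and summarize:

```python
import nucleoquant as nq

stack, truth = nq.gen_foci_field(50, 5, spot_sigma=3.0, snr=10.0, seed=202)
nuclei = nq.segment_nuclei(stack.plane("hoechst"))
table = nq.detect_foci(stack.plane("foci"), nuclei)
print(nq.summarize_foci(table, "mock-treated").to_string(index=False))
```

```
   condition  n_nuclei  mean_count  sem_count  mean_area  mean_intensity
mock-treated        50         5.0        0.0      81.72       72.886499
```

Every nucleus recovered exactly its 5 programmed foci (SEM 0), each focus
spanning ~82 px at a mean intensity of ~73 a.u. on the original projection.
A droplet field with programmed 5× protein enrichment and 3× probe
partitioning:

```python
dstack, dtruth = nq.gen_droplet_field(
    10, protein_enrichment=5.0, probe_partition=3.0, seed=7
)
res = nq.analyze_droplet_field(dstack.plane("gfp488"), dstack.plane("cy647"))
print(f"condensed fraction: {res.condensed_fraction:.5f} "
      f"(truth {dtruth.expected_metrics['condensed_fraction']:.5f})")
print(f"median protein partition: {res.droplets.protein_partition.median():.2f}")
print(f"median probe partition:   {res.droplets.probe_partition.median():.2f}")
```

```
condensed fraction: 0.02047 (truth 0.02051)
median protein partition: 5.00
median probe partition:   3.00
```

The measured condensed fraction matches the closed-form truth (Σπr²/area) to
0.2%, and both partition ratios recover their programmed values.

A command-line layer mirrors the library (`nucleoquant --help`):

```bash
nucleoquant simulate foci --out scene/ --seed 5
nucleoquant foci --stack scene/foci.ome.tif --channels hoechst,foci --out foci.csv
nucleoquant conc --n 350000 --vol 2425        # -> 0.2397 uM
nucleoquant g4scan --fasta 45S.fa --regions regions.bed --out hits.csv
```

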