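# megastitch

Fragment-based assembly and structural characterization of **megaproteins**
— single chains (like the ~4000-residue bridge-like lipid transfer proteins
LPD-3/BLTP1, VPS13, ATG2) that exceed the per-run length limit of structure
predictors. The package is for structural bioinformaticians who have
per-fragment predicted models (PDB/mmCIF with pLDDT in the B-factor column)
and want a reproducible, scriptable route from fragments to a full-length
model and the quantitative features that make the "lipid highway bridge"
argument: rod length, a continuous internal hydrophobic tunnel, the local
blockage caused by a point mutation, and the membrane-binding sequence
features at both termini.

## What it computes

1. **Fragment planning.** For a chain of length L and a predictor limit
   `max_len`, the minimal number of equal windows of length `target_len`
   with pairwise overlap ≥ `min_overlap`:
   n = ⌈(L − v)/(t − v)⌉ with starts 1 + round((i−1)(L−t)/(n−1)).
   For L = 4018, t = 1500, v = 500, limit 2500 this gives 4 fragments.
2. **Stitching.** Fragment i+1 is superposed onto the growing assembly by a
   Kabsch least-squares fit (proper rotation, det R = +1) of the Cα atoms
   shared in the planned overlap, then spliced at a single crossover
   residue so each residue comes from exactly one fragment. Junction
   quality is reported as overlap Cα-RMSD and a k-d-tree clash count.
3. **Tunnel profiling.** A central axis from sliding-window Cα centroids;
   at each axis station s the HOLE-style maximal-ball radius
   r(s) = min_a (‖x_s − x_a‖ − r_vdw(a)),
   the lining residues (atoms within r(s) + shell) and their mean
   Kyte–Doolittle hydropathy. A tunnel is *continuous* when r(s) ≥ probe
   (default 1.4 Å) at every interior station. Point substitutions are
   modelled as a volume-equivalent side-chain sphere 2.4 Å from Cα along
   the Cα→Cβ direction, giving a per-station Δradius.
4. **Sequence features.** Kyte–Doolittle hydropathy profile and TM-segment
   calling (window 19, threshold 1.6), Eisenberg hydrophobic moment
   μ = |Σ h_i (cos iδ, sin iδ)|/n at δ = 100°, the polybasic K-x-K-K motif,
   residue count and molecular weight.
5. **Synthetic benchmarks.** A ground-truthed hollow helical tube generator
   plus a fragmenter that scatters planned fragments into random rigid
   frames with Gaussian coordinate noise — the exact inverse of the
   stitcher, so every stage is testable without a predictor run.

## Worked example

```
megastitch simulate --n-res 900 --length 300 --lumen-radius 6.0 \
    --fragments 3 --overlap 75 --sigma 0.5 --seed 7 --outdir sim
megastitch run --fragments sim/fragment_1.pdb --fragments sim/fragment_2.pdb \
    --fragments sim/fragment_3.pdb --plan sim/truth.json --outdir sim/out --seed 7
```

`sim/out/report.json` then contains (this run's actual output):

```
"geometry": {
  "rod_length_A": 300.76, "rod_length_nm": 30.08,
  "axis_arclength_A": 282.0,
  "tunnel": {"continuous": true, "min_radius_A": 4.85,
             "mean_lining_hydropathy": 4.17}
},
"stitch": {"junction_rmsd_A": [1.20, 1.18], "clash_count": 0,
           "total_residues": 900}
```

Reading: the assembled model is a 30 nm rod; the two junctions closed with
~1.2 Å overlap Cα-RMSD (the expected σ√6 for two copies carrying 0.5 Å
per-coordinate noise) and no steric clashes; the tunnel stays open along
the whole interior (the 0.5 Å noise narrows the ideal 6 Å lumen to a
4.9 Å minimal radius) and is strongly hydrophobic (mean lining hydropathy
4.2, Ile/Leu/Val wall). For a real megaprotein, `megastitch run
--lpd3-preset` pins the 4018-residue planning scheme, the terminal
annotation regions (a.a. 1–72 and 3945–4018) and the G200E tunnel-entry
scan; supply your own FASTA/fragment/model files.

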