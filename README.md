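# lbdtandem

Toolkit for analyzing tandem ligand-binding-domain (LBD) multiplications in
TGFβ-family receptors:

- **`synthetic_data`** — generators with known ground truth: clock-evolving
  protein clades with an internal domain duplication (JTT + discrete-gamma
  site rates on a focal-centered star topology), toy ligand/linker 3-D
  structures (threading vs wrapping paths), and receptor gene models with a
  duplicated exon pair.
- **`seqio_domains`** — FASTA IO, affine-gap global/local alignment
  (BLOSUM62, Gotoh), tandem-domain annotation by iterative Smith–Waterman
  with masking, and inter-domain linker lengths.
- **`conservation`** — intra-protein identity profiles relative to the
  membrane-proximal (`in`) domain copy and ligand-contact epitope retention
  scoring from editable TSV epitope specs.
- **`molclock`** — pairwise ML amino-acid distances under JTT + discrete
  gamma (pairwise deletion), site-bootstrap variances, weighted clock
  regression of distance on divergence time, and duplication-specific rates.
- **`linker_geometry`** — PDB parsing, linker span detection by core-motif
  match with G/S flank extension, the octant spatial-embedding metric
  (embedded ⇔ ligand heavy atoms in ≥5 of 8 octants within 5 Å of the Cα),
  misplaced-model QC filtering, and the minimal-bivalent-linker cutoff.
- **`pipeline` / `cli`** — end-to-end orchestration with one seed, named
  per-stage substreams, and byte-reproducible outputs.

## Rate convention

The clade rate `r` is defined on the **pairwise path**: expected distance
`d = r · T` where `T` is the tabulated divergence time of the pair. Per
lineage this corresponds to `r/2` when the pair time is split symmetrically.
The simulator, divergence tables, and the regression all use this single
convention, so the fitted slope recovers the simulated `r` directly.

## CLI

```sh
lbdtandem simulate --seed 1 --out-dir runs/sim --n-taxa 5 --times 40,70,100,130
lbdtandem annotate-domains proteins.fa --reference ref_lbd.fa --min-score-frac 0.4
lbdtandem conservation proteins.fa --reference ref_lbd.fa \
    --epitope src/lbdtandem/data/epitopes/tgfbr2_like.tsv --mode strict --out-dir runs/cons
lbdtandem clock domains.fa --times divergence_times.tsv --alpha 1.0 --k 4 \
    --boot 1000 --seed 1 --through-origin --out-dir runs/clock
lbdtandem linker model_*.pdb --radius 5.0 --min-octants 5 --top-n 3 --out-dir runs/geom
lbdtandem run --seed 1 --out-dir runs/demo       # full synthetic demo
lbdtandem report runs/demo
```

`lbdtandem run` accepts a YAML config (`--config cfg.yaml`); every key of
`lbdtandem.pipeline.RunConfig` is a valid entry and unknown keys are
rejected by name. Re-running with the same config and seed is
byte-identical.

## Notes

- Epitope specs under `src/lbdtandem/data/epitopes/` are illustrative
  fixtures, not authoritative contact sets; supply your own TSV
  (`group  ref_pos_1based  contact_type`).
- The octant frame is axis-aligned in the model's global coordinates by
  default (joint translation never changes counts; joint rotation can).
  Use `--frame pca` for a rotation-covariant ligand-PCA frame, or
  `lbdtandem.linker_geometry.rotation_sensitivity` for a sensitivity report.
- `r_dup = d_dup / r_clade` has units of time; the dimensionless relative
  rate `d_dup / (r_clade · t_dup)` is also reported when a duplication age
  is supplied.
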