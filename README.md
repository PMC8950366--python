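# hemedist

Semi-quantitative discrimination of cytochrome P-450 (CYP2D6) substrates and
missense variants from the **Fe-heme / reactive-atom distance**.

CYP2D6 is a highly polymorphic phase-I enzyme. Whether a ligand is actually
oxidised depends on whether the atom undergoing the metabolic reaction sits
close to the heme iron of the catalytic centre — and missense variants
(star alleles such as \*14A, \*51, \*110, \*122) can push that atom towards
or away from the iron. `hemedist` implements a desk-scale pipeline around
this structural discriminant for structural bioinformaticians and
toxicologists who want to rank ligand × variant combinations:

- **geometry** — per-frame distance `d(t) = |r_reactive(t) − r_Fe(t)|`
  (reported in nm) over a trajectory, plus Kabsch-superposed RMSD series of
  protein C-alpha and ligand atoms;
- **statistics** — per-complex mean ± SE over frames, independent two-sample
  t-tests (pooled-variance Student by default, Welch and an
  effective-sample-size correction as options, α = 0.05), sustained-excursion
  detachment detection;
- **calls** — substrate likelihood against the probe envelope
  (`probe_like` / `minor_substrate` / `poor_or_non_substrate`) and variant
  effect versus the reference allele \*1
  (`likely_enhanced` / `likely_reduced` / `unchanged`);
- **variant bookkeeping** — built-in allele definitions
  (\*14A = P34S+G169R+R296C+S486T, \*51 = R296C+E334A+S486T, \*110 = G445R,
  \*122 = V370I), sequence-level mutation application, the
  ΔΔG < 1 kcal/mol limited-stability-effect rule, and heme-proximity
  annotation of mutation sites;
- **conservation** — MSA column conservation at a reference-mapped position
  and scans for the heme-binding motif `GX[HR]XC[PLAV]G` (strict, and
  relaxed at the +2 position two residues downstream of the
  iron-coordinating Cys);
- **synthetic data** — an exact-discretisation Ornstein–Uhlenbeck generator
  standing in for MD distance traces, toy protein–heme–ligand complexes,
  trajectory embedding, and alignments with exactly controlled substitution
  counts. Shipped scenario presets carry the reported stationary means for
  ten ligand × allele complexes plus a detachment scenario for OTA:\*122.

Trajectories are read and written as multi-model PDB; alignments as aligned
FASTA or Clustal.

## Worked example

```python
from hemedist import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(seed=1, n_frames=5000, out_dir="out"))
print(bundle.complexes[["label", "mean_nm", "se_nm", "substrate_call"]])
print(bundle.effects[["ligand", "allele", "delta_nm", "p_value", "effect_call"]])
```

prints (abridged):

```
                label  mean_nm    se_nm        substrate_call
  dextromethorphan:*1 0.439724 0.001180            probe_like
         bufuralol:*1 0.405465 0.001002            probe_like
               OTA:*1 0.500108 0.001017       minor_substrate
 dextromethorphan:*51 1.156589 0.001018 poor_or_non_substrate
             OTA:*110 0.446776 0.001006            probe_like
             OTA:*122 0.945766 0.002325 poor_or_non_substrate

  ligand allele  delta_nm       p_value     effect_call
     OTA   *110 -0.053332 4.353919e-285 likely_enhanced
     OTA   *14A  0.123811  0.000000e+00  likely_reduced
     OTA    *51  0.221557  0.000000e+00  likely_reduced
```

Reading: the two probe substrates sit ≈0.41–0.44 nm from the iron
(probe-like), ochratoxin A in the wild-type enzyme sits further out
(0.50 nm — a minor substrate), and the \*110 variant pulls OTA's reactive
atom ≈0.053 nm closer than wild type (p ≪ 0.001 — likely enhanced
oxidation), while \*14A/\*51 push it away and \*122 detaches outright (onset
5 ns, mean ≈0.95 nm). Each run also writes `complexes.tsv`, `effects.tsv`,
per-series TSVs and `report.json` (with seed and config hash) to `out/`.

The same analyses are available from the shell:

```bash
hemedist all --seed 1 --out out/            # end-to-end synthetic run
hemedist simulate --preset "OTA:*110" --out sim/
hemedist analyze --config run.toml          # trajectories and/or presets
hemedist conservation --msa aln.fasta --ref-id REF --ref-position 445
```

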