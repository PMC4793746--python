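# scaffkit

Semi-automated genome assembly improvement and anchoring:

* **Misassembly splitting** — scaffolds carrying genetic markers from more
  than one linkage group are split where spanning mate-pair coverage
  vanishes (or discordance spikes), preferring an existing N-gap.
* **Fusion / junction remodelling** — clusters of discordant mate pairs
  propose inserting a free scaffold into another's gap (*fusion*) or
  end-joining two scaffolds across a 100-N gap (*junction*); edits are
  applied only in the orientation that renders the supporting pairs
  concordant, and validated afterwards.
* **Gap re-estimation** — every N-run is resized so spanning, correctly
  oriented pairs recover the library's expected median insert, sequentially
  per library with per-library support thresholds (30/2/1).
* **Anchoring** — markers are filtered (≤20 % missing, ≥10 % het-or-dominant,
  ≥1.5 % homozygous), pairwise two-point LOD is computed by EM under the F2
  selfing model (dominant codes marginalised, both phases tried), linkage
  groups form by single-linkage at a LOD threshold, scaffolds are seriated
  by a UPGMA-like procedure on mean cross-scaffold LOD and refined by
  steepest-ascent permutation/orientation search maximising
  `sum (1 - (x_j - x_i)/n) * LOD_ij` over cross-scaffold marker pairs.
  Pseudo-molecules are emitted as FASTA + AGP v2.0 with 100-N spacers.
* **Edit ledger** — every split/fusion/junction/resize/rename/anchor is a
  replayable record enabling byte-exact reproduction and exact coordinate /
  GFF3 lifting.
* **Simulator** — a fully truth-annotated synthetic dataset (genome, flawed
  assembly with planted chimeras / excisions / adjacent splits / mis-sized
  gaps, FR mate pairs in SAM, an F2 selfed marker population under the
  Haldane model) so the whole pipeline is testable offline.

## CLI

All functionality is under a single entry point:

```bash
scaffkit simulate --config sim.yaml --out data/      # synthetic dataset
scaffkit run --assembly data/scaffolds.fasta --sam data/pairs.sam \
             --markers data/markers.tsv --probes data/probes.fasta \
             --out results/                           # full pipeline
```

Individual stages: `classify-pairs`, `filter-markers`, `lod`,
`group-markers`, `place-markers`, `assign-scaffolds`,
`detect-misassemblies`, `remodel` (link detection + proposals + apply +
validate; `--report-only` to inspect), `report-region`, `reestimate-gaps`,
`anchor`, `digest`, `superscaffold`, `lift-gff`, `consensus-gff`.
Run `scaffkit COMMAND --help` for options.

## Layout

```
src/scaffkit/
  io_formats/    FASTA, AGP v2.0, SAM pairs, marker-matrix TSV, GFF3, ledger
  assembly.py    Assembly + EditLedger + coordinate lifting / replay
  simulator.py   truth-annotated synthetic data
  readpairs.py   pair classification, dedup, evidence tracks
  markers.py     filtering, two-point EM/LOD, grouping, placement, assignment
  misassembly.py conflict candidates, breakpoint localisation, splitting
  remodler.py    discordant clusters, fusion/junction proposals, validation
  gaps.py        N-run detection and insert-based resizing
  anchoring.py   similarity, seriation, score, optimizer, pseudo-molecules
  pipeline.py    orchestration, liftover, consensus annotation, digest
  benchmarks.py  seed-controlled standard benchmarks used by acceptance
  cli.py         click command group (`scaffkit`)
```
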