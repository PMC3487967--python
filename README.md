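# abmtki

A multi-scale agent-based simulator of vascularised brain-tumor growth and
its response to receptor-kinase-inhibitor (TKI) treatment.

Four coupled scales run on a 2-D square lattice (20 µm spacing, 1 h steps):

* **molecular** — every tumor cell carries a small ODE network: growth-factor
  ligand binding → receptor activation → effector (PLCγ-like) turnover,
  coupled to a CDh1/cycCDK cell-cycle switch that gates division.  The rate
  of change of the active effector is the cell's *migration potential*.
* **cellular** — glucose thresholds decide death / reversible quiescence /
  activity; the migration potential selects migration vs. proliferation;
  offspring and migration targets maximise `ψ·G/F + (1−ψ)·ε` over free
  neighbour sites.
* **micro-environmental** — explicit finite-difference reaction–diffusion
  fields (glucose, oxygen, TGFα, VEGF, fibronectin, drug) with zero-flux
  boundaries, transvascular exchange at vessel sites and uptake/secretion at
  tumor sites.
* **tissue** — stochastic tip-endothelial-cell migration under VEGF
  chemotaxis and fibronectin haptotaxis, with sprout branching (after 18 h)
  and anastomosis.  Treatment is delivered through this growing vasculature
  and blocks the receptor via quasi-steady-state Michaelis–Menten occupancy.

The `analysis` module adds the derived statistics: phenotype census series,
proliferation rate, paired survival percentage, a ±10 % local sensitivity
scan of the signaling network, and a fold-change robustness protocol on the
full model (robustness index `R`, coefficient of variation of outcomes).

**Kinetic table.** The published model's full kinetic tables are in
supplementary material that is not redistributable here; the package ships a
documented stand-in network with the same topology and interface
(`abmtki.signaling.default_pathway`).  Any user-supplied rate-law table (TSV,
see `save_rate_table`/`load_rate_table`) can replace it via the
`pathway.table_path` config key, which makes all downstream machinery exact
when the original coefficients are available.

## Command line

```bash
# drug-free growth, 150 h, all outputs into ./out
abm-tki run --hours 150 --drug off --seed 1 --outdir out

# treated run from a config file
abm-tki run --config my_config.yaml --drug on --hours 300 --outdir out_tki

# +/-10% sensitivity scan of the signaling network
abm-tki sensitivity --out sensitivity.csv

# fold-change robustness experiment (reduced replicate count)
abm-tki robustness --baseline-runs 10 --out robustness.csv

# summarise a finished run directory
abm-tki report out
```

`run` writes a metrics CSV (hourly phenotype census, EC count, mean effector
rate, migration/division events), per-field CSV snapshots, the vessel
edge-list, the agent table, the resolved config and a manifest JSON that
fully reconstructs the run.  An empty/omitted config gives the documented
defaults (200×200 lattice, parent vessel with 6 tips near the left boundary,
40-cell cluster, ψ = 0.7).

Configuration is a single YAML mapping validated against
`abmtki.config.SimConfig`; unknown keys are rejected with named-field
errors.  `abmtki.config.small_test_config()` and `robustness_config()` are
reduced-scale presets (60×60) used by the tests and the acceptance report.

## Layout

```
src/abmtki/
  signaling.py     per-cell ODE network, drug blockade, rate-table I/O
  microenv.py      reaction-diffusion fields on the lattice
  agents.py        phenotype switching, migration, division placement
  angiogenesis.py  tip-cell migration distribution, branching, anastomosis
  simulator.py     initialisation and the hour-stepped orchestration
  analysis.py      census metrics, sensitivity and robustness statistics
  io_cli.py        config loading, output writers, CLI entry points
  config.py        validated configuration models and presets
```
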