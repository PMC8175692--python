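# conductsim

Event-driven simulator of the human cardiac conduction system, built as a
small library of reusable discrete-event components plus a monolithic
scheduling-based reference implementation for equivalence checking.

The modular model chains three physiological components between the
sinoatrial (SA) input and the ventricular output:

```
S ──▶ Pacemaker ──▶ RefractoryGate ──▶ AVConductionDelay ──▶ V
         ▲ reset ◀──────┘
```

* **Pacemaker** — passes signals through and fires on its own when its
  timer has been silent for one period (AV-nodal escape rhythm). Its
  reset is a separate input fed from the refractory gate's output, so
  blocked signals cannot restart the escape countdown.
* **RefractoryGate** — drops events arriving within `d_refrac` of the
  last event that passed (strict inequality: boundary equality blocks).
* **AVConductionDelay** — holds each event and releases it after
  `d_min + d_amp·exp(−t_rec/τ)`, where `t_rec` is the recovery time since
  the last released event. Any recovery→delay map can be injected.

An interbeat tracker on the ventricular output records `(time, interval)`
samples online. The PVC extension (`build_pvc_conduction`) adds a second
refractory gate for the ventricles, two OR gates, one AND gate and a
boundary `pvc` trigger input: triggers during the ventricular refractory
period are swallowed, triggers outside it produce an immediate beat, and
every beat (conducted or ectopic) opens a refractory window.

The engine (`conductsim.engine`) is a deterministic discrete-event kernel
with zero-delay propagation: all consequences of one event instant are
resolved synchronously by fixpoint iteration, handlers observe pre-instant
state only, and each output fires at most once per instant.

## CLI

```sh
# run a model from a config file
conductsim simulate --config examples/modular.yaml --out-dir out/ [--model modular|monolithic|pvc] [--seed N] [--stop SECONDS]

# modular vs monolithic interbeat comparison
conductsim compare --config examples/modular.yaml --out-dir out/ --tol 1e-6

# PVC scenario
conductsim pvc --config examples/pvc.yaml --out-dir out/

# wiring diagram (Graphviz DOT, generated from the model structure)
conductsim diagram --model pvc -o pvc.dot
```

Config files are YAML (or JSON) with keys

```yaml
model: modular          # modular | monolithic | pvc
t_start: 0.0
t_stop: 60.0
seed: 1
params:
  d_refrac_s: 0.5
  period_s: 2.0
  av: {d_min_s: 0.1, d_amp_s: 0.1, tau_s: 1.0}
  d_refrac_ventricle_s: 0.3     # pvc model only
stimulus:
  kind: switching               # constant | switching | trace | none
  choices_s: [0.4, 0.8, 1.2]    # interval switches every 5–10 s
pvc_trigger: {times_s: [4.6]}   # pvc model only
```

Outputs are diff-friendly CSV/JSON (`traces.csv` with `time_s,port` rows,
`interbeat.csv`, `provenance.json`, optional `comparison.json`), all
byte-reproducible from (config, seed).

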