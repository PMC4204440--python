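# glyqsp

A quantitative systems pharmacology model of glycine modulation of
cortical-striatal excitation/inhibition balance, built for researchers
studying negative symptoms in schizophrenia and the puzzling non-monotonic
clinical dose-responses of glycine-site interventions (glycine, D-serine,
sarcosine, GlyT1 inhibitors).

## The science

Glycine is the obligatory co-agonist at the NMDA receptor's glycine-B site,
but its potency differs across NR2 subunits. NR2A/NR2B receptors dominate
pyramidal-pyramidal (e-e) synapses and NR2C/NR2D receptors
pyramidal-interneuron (e-i) synapses; each class is described by a Hill
relation

    g(Gly) = g_max · Gly^n / (Gly^n + EC50^n)

When the e-e class has the steeper Hill slope — as the neurodevelopmental
NR2B bias of schizophrenia favors — the **e-i/e-e potentiation ratio**
dips below 1 over a low-micromolar window: raising glycine first
potentiates excitation more than inhibition (clinical benefit), then the
advantage reverses as both saturate. The network outcome is an
**inverse-U dose-response** whose optimum tracks the ratio minimum.

Two further ingredients constrain and shape the effect:

* **GlyT1 thermodynamics.** The electrogenic 2Na⁺/Cl⁻/glycine
  cotransporter pins extracellular glycine at equilibrium:
  `Gly_out = Gly_in·(Na_in/Na_out)²·(Cl_in/Cl_out)·exp(F·Vm/RT)`.
  Over the physiological box this stays in the low micromolar range —
  exactly where the ratio minimum sits.
* **Receptor internalization** at high glycine (EC50 ≈ 40 µM) caps the
  usable range from above.

The package implements the full cascade: Hill pharmacodynamics per synapse
class → a 20-pyramidal/10-interneuron conductance-based spiking network
with schizophrenia pathology → Balloon-model BOLD and a ventral-striatum
medium-spiny-neuron population → a weighted composite (40% cortical / 60%
striatal) mapped linearly to PANSS-negative change, plus steady-state
receptor-competition pharmacology, a synthetic clinical-trial generator,
and range-based sensitivity analysis. See `docs/methods.md` for equations,
parameter provenance and limitations.

## Worked example

```python
from glyqsp import (HillParams, SynapseClassPD, find_ratio_extremum,
                    classify_dose_response, max_equilibrium_over_ranges)

pd_ = SynapseClassPD(ee=HillParams(ec50=0.35, slope=1.84),   # NR2A/B class
                     ei=HillParams(ec50=0.25, slope=1.1))    # NR2C/D class

ext = find_ratio_extremum(pd_, window=(0.01, 100.0))
print(f"minimum e-i/e-e ratio {ext.ratio_star:.3f} at {ext.gly_star:.2f} uM glycine")
print("classification:", classify_dose_response(pd_).value)

val, corner = max_equilibrium_over_ranges()
print(f"transporter ceiling {val:.2f} uM at Na_in={corner.na_in}, "
      f"Cl_in={corner.cl_in}, Gly_in={corner.gly_in} mM, Vm={corner.vm} mV")
```

prints

```
minimum e-i/e-e ratio 0.937 at 1.26 uM glycine
classification: beneficial_U
transporter ceiling 2.28 uM at Na_in=20.0, Cl_in=12.0, Gly_in=5.0 mM, Vm=-40.0 mV
```

So for these subunit parameters inhibition is potentiated *less* than
excitation around 1.3 µM glycine (ratio 0.937 < 1), the minimum falls in
the physiological 0.5-10 µM band (`beneficial_U`), and the transporter
equilibrium caps free glycine at ≈ 2.3 µM — the circuit can actually reach
the beneficial window, but not far beyond it. Running the spiking network
across a glycine grid (`glyqsp dose-response`) turns this ratio minimum
into an interior maximum of the composite network outcome.

## Command line

A thin CLI wraps the library; every run writes delimited outputs plus a
`manifest.json` (config hash, seed, version) for reproducibility:

```bash
glyqsp dose-response   --seed 1 --outdir out/   # full pipeline over a glycine grid
glyqsp transporter-range                        # equilibrium glycine ceiling
glyqsp network-sim --glycine 1.0                # one cortical circuit run
glyqsp bold-sim                                 # Balloon step response
glyqsp msn-sim                                  # one medium spiny neuron
glyqsp make-fixtures                            # synthetic 34-trial database
glyqsp calibrate --trials t.tsv --proxies p.tsv # linear PANSS calibration
glyqsp sensitivity --parameter pathology.nmda_reduction
```

Configuration is YAML overlaying `glyqsp.config.default_config()`.

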