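# seedwater

Water requirement and growth indicators for forest-tree seedlings raised
under automated (soil-water-tension-triggered) drip irrigation.

Nurseries producing seedlings for forest restoration rarely know how much
water a species actually needs, and routinely over-irrigate. This package
implements the analysis for deficit-irrigation seedling experiments in
which four water-replacement levels (V1..V4, roughly 40% to 100% of the
requirement) are realised by drip emitters of different flow rates sharing
a single tension-actuated valve. It targets researchers and nursery
irrigation engineers working with two-phase trials (tube seedling phase,
then pot growth phase) on species such as *Schizolobium parahyba*,
*Cytharexylum myrianthum* and *Ceiba speciosa*.

## The indicators

**Growth plant factor (Gpf).** A Ky-style deficit-sensitivity slope for a
growth variable Va (height, cm, or collar diameter, mm):

    1 − Va/Vm = Gpf · (1 − Vola/Volm)

where Vola is the volume applied to a treatment, Volm the full-replacement
(V4) volume, and Vm the asymptotic no-deficit value of the variable. Vm is
not observed: it is chosen so that the OLS intercept of the deficit
regression is exactly zero, and Gpf is the slope at that Vm. The original
procedure iterated with a spreadsheet solver; `seedwater` evaluates the
closed form

    Vm* = mean(Va) − x̄ · S_xVa / S_xx,   Gpf = −S_xVa / (Vm* · S_xx)

(x = 1 − Vola/Volm; S denotes centred sums of squares/cross-products) and
also ships the bracketed root-finder as a cross-check. Gpf < 1 means the
relative growth loss is smaller than the relative water deficit
("low sensitivity", as for the FAO yield response factor Ky).

**Water efficiency (WE).** Growth per litre applied, WE = Vg / Tva: HWE in
cm/L for height, DWE in mm/L for diameter, per species × treatment × phase,
with optional Bartlett checks and Tukey-HSD compact letter display on
replicate-level data.

**Growth response and quality.** OLS linear/quadratic fits of size against
applied volume (slopes in cm/L, mm/L) and the H/D quality ratio (cm/mm,
acceptable below 8.0).

**Simulator.** A tension-triggered controller model (one sensor in the
wettest treatment gates all lines, so applied volumes stay proportional to
emitter flows) plus a deficit-law growth generator with known true
parameters, used to validate the estimators by parameter recovery.

## Worked example

The reconstructed published experiment ships with the package
(`build_inpaper_fixture`: final size = WE × applied volume, inverting the
WE definition). Running `python examples/02_deficit_sensitivity.py` prints:

```
species        response   Gpf     Vm       sensitivity
C_myrianthum   height    0.1904   26.828  low sensitivity
C_myrianthum   diameter  0.3701    4.731  low sensitivity
C_speciosa     height    0.4702   38.091  low sensitivity
C_speciosa     diameter  0.2961    6.843  low sensitivity
S_parahyba     height    0.4291   41.848  low sensitivity
S_parahyba     diameter  0.2871    8.586  low sensitivity

max Gpf = 0.470: all six fits stay below 0.5, ...
```

Each row is one species × growth variable: Gpf is the deficit-sensitivity
slope (dimensionless) and Vm the fitted asymptotic size (cm for height, mm
for diameter). All six values sit below 0.5 — these species lose
proportionally little growth under water deficit, so moderate deficit
irrigation is a viable water-saving strategy in the nursery.

The other examples rebuild the water-efficiency table
(`01_published_experiment.py`), fit the growth-vs-volume slopes and check
H/D quality (`03_growth_response.py`), and run the simulator + estimator
recovery loop (`04_simulated_recovery.py`).

The same pipeline is available from the shell:

```bash
seedwater fixture --out fx
seedwater fit-gpf --in fx/observations.csv --out fx/gpf.csv
seedwater efficiency --in fx/observations.csv --out fx/we.csv
seedwater report --in fx --out fx/report.md
```

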