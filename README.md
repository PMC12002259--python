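# ringpool

Equilibrium oligomer-pool analysis for ring-forming single-strand-
annealing proteins, built around single-molecule mass photometry.

RAD52, the human single-strand-annealing protein, is famous for its
ring structures — yet at the low-nanomolar concentrations where it
actually anneals DNA, most of the protein is monomers and short
oligomers.  `ringpool` is for biophysicists and structural biologists
who want to quantify that balance: it turns lists of single-particle
masses (one calibrated mass per landing event) into per-oligomer
abundances, and fits them with a thermodynamic self-assembly model that
explains why rings behave like a reservoir.

## The model

Open chains grow isodesmically — every monomer addition shares one
dissociation constant K_d — giving the geometric law
c_open(n) = K_d (c1/K_d)^n.  An open n-mer may close into a ring,
gaining one bond but paying elastic bending energy away from the
optimal ring size n_o:

    K_c(n) = K_c0 · exp(−½ ((n − n_o)/σ_ring)²)

with energies in units of k_BT.  Closed rings dominate near n_o
(ΔG_ring = ln K_c0 ≈ 14 k_BT for RAD52) and are negligible for small n.
Above a critical concentration (~2–5 nM) added protomers condense into
rings while the dilute pool of monomers and short oligomers stays
nearly constant — a vapor–liquid-like buffering that keeps the
annealing-active species at a fixed concentration.

The package also provides the surrounding analysis: multi-Gaussian
histogram deconvolution with calibration-bounded peak widths and
AIC-based component selection, conversion of event counts to species
concentrations, the empirical linear ring model
c_ring = (c_protomer − c_crit)/n_avg, Hill fits of cooperative ssDNA
binding, single-exponential annealing kinetics, and a fully seeded
synthetic-data generator that emulates mass-photometry acquisitions.

## Worked example

```python
import ringpool as rp

# equilibrium species distribution at 2 nM total protomer,
# using the fitted RAD52 parameters (Kd=14 nM, Kc0=1.9e6,
# n_o=10.8, sigma_ring=0.79)
dist = rp.equilibrium_distribution(2.0, rp.RAD52_FITTED)
pools = rp.pool_summaries(dist)
print(f"short pool {pools.short_pool:.3f} nM, "
      f"ring pool {pools.ring_pool:.5f} nM, ratio {pools.ratio:.0f}")

# critical concentration for ring formation (maximum curvature)
print(f"c_crit = {rp.critical_concentration(rp.RAD52_FITTED):.2f} nM")

# full synthetic round trip: simulate a titration, deconvolve the
# histograms, convert counts to concentrations, refit the model
spec = rp.SimulationSpec(seed=1)          # 10-200 nM, 4x2000 events
events = rp.simulate_titration(spec)
table, fit = rp.analyze_titration(events, spec.monomer_mass, spec.calib,
                                  seed=1, n_boot=0)
print(fit.summary())
```

prints

```
short pool 1.704 nM, ring pool 0.00936 nM, ratio 182
c_crit = 2.02 nM
Ring assembly model — global fit
============================================
parameter         estimate       boot SE
kd (nM)             14.794            --
kc0             2.6597e+06            --
n_opt               10.855            --
sigma_ring         0.74507            --
objective (weighted SSR): 0.161399
```

At 2 nM total protomer the dilute pool outnumbers rings ~180-fold; the
curvature of the ring pool peaks at ≈2 nM, the model's critical
concentration; and the global fit to a simulated titration recovers the
generating K_d = 14 nM within ~6% (ring-shape parameters are recovered
with more blur because adjacent ring peaks overlap in mass).

A `ringpool` command-line tool wraps the same pipeline
(`simulate`, `calibrate`, `deconvolve`, `fit-model`, `binding-fit`,
`annealing-fit`, `analyze`); every report embeds the tool version,
config hash and seed, and identical inputs plus seed reproduce outputs
byte for byte.

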