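# guvkit

Quantitative analysis of actin-driven remodeling of giant unilamellar
vesicles (GUVs) from two-channel fluorescence time lapses, together with a
physical model of why branched actin networks stabilize lipid microdomains.

Reconstituted branched (Arp2/3-nucleated) actin networks polymerized at the
outer surface of a GUV form a shell that thickens, breaks symmetry, and can
grow into a propulsive comet. On phase-separated membranes the network
assembles on the liquid-disordered (Ld) domains and arrests their
coalescence. `guvkit` provides, as an importable library plus a thin CLI:

* **synthetic imaging** (`guvkit.synth`) — equatorial cross-sections of
  GUVs (membrane ring + actin shell/comet + Ld arcs + Poisson/Gaussian
  noise) with embedded ground truth, so every downstream measurement is
  testable without raw microscopy data;
* **morphometry** (`guvkit.morphometry`) — contour segmentation and the
  standard descriptors
  `d_GUV = 2 √(Area/π)`,
  `Ellipticity (%) = 100 · L_MaxPerp / MaxFeret`,
  actin shell thickness (longest membrane-to-network-edge radial distance)
  with its symmetry-breaking orientation, structure classification
  (symmetric shell / asymmetric shell / comet), and OLS growth-rate fits;
* **radial profiling** (`guvkit.profiles`) — 360 per-degree membrane-peak
  intensities, per-channel normalization to [0, 1], Ld-domain calling where
  the normalized lipid signal exceeds 0.2, and the normalized actin
  fluorescence on Ld domains;
* **domain dynamics** (`guvkit.dynamics`) — per-vesicle domain-count
  trajectories, the domain number ratio `N_t / N_0` (t = 10 or 60 min),
  n_d categories (n_d = 2, 2 < n_d ≤ 10, n_d > 10), and the study's testing
  policy (exact Mann–Whitney U, Wilcoxon signed-rank, Welch's t with
  n.s./*/**/*** tiers);
* **coalescence physics** (`guvkit.physics`) — the Saffman–Delbrück
  mobility `D(r) = k_BT/(4π η_m) · ln(η_m/(η_f r))`, the neighbor contact
  time `τ = R²/4D`, the actin-corona overhang `v_gel · t` and its
  mesh-size blocking criterion, and a Brownian diffusion–coalescence
  simulator of domains on a spherical vesicle in three modes
  (bare / spVCA-coated / actin).

With the default parameters (η_m = 10⁻⁸ Pa·m·s, η_f = 10⁻³ Pa·s,
k_BT = 4.1×10⁻²¹ J) a 1 µm Ld domain has D ≈ 8×10⁻¹⁴ m² s⁻¹, meets its
neighbor at R ≈ 5 µm in τ ≈ 80 s, and in that time an actin corona growing
at 2.5 nm s⁻¹ overhangs the domain edge by ≈ 200 nm — more than the ~100 nm
network mesh size, which is why coalescence is sterically blocked.

## Worked example

`examples/04_coalescence_simulation.py` runs the simulator in its three
modes from one seed (34 initial domains on a 10 µm-radius vesicle, first
acquisition frame one minute after demixing) and prints:

```
mode      N0  N10  N60  ratio_60
bare      17    4    1      0.06
spvca     27    9    3      0.11
actin     19   19   19      1.00

Analytic scales: D(1 um) = 7.5e-14 m^2/s, contact time tau = 83 s,
corona overhang in tau = 208 nm (> 100 nm mesh size -> blocked).
```

Bare vesicles coarsen essentially completely (ratio_60 ≈ 0.06), the
spVCA coat slows but does not stop coalescence, and the actin corona
freezes the count (ratio_60 = 1). The other examples cover rendering +
morphometry round-trips, growth-rate fitting, radial profiling with domain
calling, and the packaged end-to-end pipelines (`guvkit.io.run_pipeline`,
also exposed as `guvkit run/synth/measure/profile/dynamics/simulate` on the
command line).

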