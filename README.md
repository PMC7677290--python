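# sphereq

Passive electrophysiology of spherical cells whose interior does not
conduct — most prominently white adipocytes, where a unilocular lipid
droplet fills 90–99% of the cell and confines the cytoplasm (and all
intracellular current flow) to a ~0.5 µm shell under the plasma membrane.
Such a cell cannot be assumed equipotential the way an ordinary sphere can,
and the standard 1D cable theory for neurites does not apply either.

`sphereq` is for experimental electrophysiologists and modellers who need
to quantify what a patch pipette actually sees on such a cell: the steady
voltage profile and input resistance, charging/discharging dynamics, and
the distortion (space-clamp error) of voltage-clamp recordings.

## The model

With azimuthal symmetry around the pipette at the north pole, Kirchhoff's
current law on thin latitude bands of the shell gives, in the limit of fine
bands, a spherical analogue of the cable equation for the membrane voltage
V(θ, t):

    τ ∂V/∂t = −V + (λ²/ρ²) (1/sin θ) ∂/∂θ ( sin θ ∂V/∂θ ) + I_ext R_m

with membrane time constant τ = r_m c_m and electrotonic length
λ = √(r_m d / r_i), where c_m is the specific membrane capacitance, r_m the
specific membrane resistance, r_i the cytoplasmic resistivity, ρ the cell
radius and d the shell thickness.  The behaviour is governed by just τ and
the ratio ρ/λ.  The pipette is an equipotential cap θ ≤ θ_a with no
membrane under it; in current clamp all injected current exits the cap rim
as the flux condition V′(θ_a) = −I r_i/(2π d sin θ_a), and the south pole
is sealed, V′(π) = 0.

The steady state is the conical-Legendre pair
V(θ) = b [Q_{ν⁺}(cos θ) + Q_{ν⁻}(cos θ)] with
ν± = −½ ± ½√(1 − 4ρ²/λ²), evaluated at arbitrary precision; dynamics use a
conservative finite-volume method of lines (the discrete band circuit
itself) advanced either by an exact spectral propagator or by stiff BDF.
Single-compartment and sealed-cable reference models
(λ_cable = √(d_cable r_m / 4 r_i)) are built in for comparison, including
the closed forms 1 − e^{−t/τ} (half-max at τ ln 2 ≈ 0.693τ) and
erf(√(t/τ)) (half-max at (erfinv ½)² τ ≈ 0.227τ).

See `docs/methods.md` for assumptions, numerics and known limitations.

## Worked example: the adipocyte

A typical adipocyte has ρ = 40 µm, d = 0.5 µm, c_m = 1 µF/cm²,
r_m = 100 kΩ·cm², r_i = 100 Ω·cm, and a 2 µm pipette (θ_a = 0.025):

```
$ sphereq adipocyte-report
{
  "tau_ms": 100.0,
  "lambda_um": 2236.0679774997893,
  "lambda_over_rho": 55.90169943749474,
  "theta_a_rad": 0.02500260489936114,
  "nu_plus": -0.00032010246558844546,
  "R_in_MOhm": 498.67295726944786,
  "R_compartment_MOhm": 497.3591971621731,
  "overestimate_percent": 0.26414714250200255,
  "t_half_over_tau": 0.6906655888343333,
  "conservation_error": 2.0251165056743687e-05,
  ...
}
```

Reading these numbers: λ ≈ 2200 µm is ~56× the radius, so the adipocyte is
electrotonically compact — the whole membrane charges nearly uniformly.
The input resistance (499 MΩ) exceeds the single-compartment value
r_m/(4πρ²) = 497 MΩ by only 0.26%, the excess being the spreading
resistance of current funnelling through the narrow pipette cap.  The
half-maximum charging time is 0.691τ, marginally faster than the
single-compartment τ ln 2 ≈ 0.693τ for the same reason.  The conservation
figure is the relative mismatch of the leak-current identity
(2πρ²/r_m)∫V sin θ dθ = I_ext, the standard accuracy self-check.

The same quantities are available from Python:

```python
import sphereq as sq
membrane, geom, electrode, stim = sq.loads_config(sq.adipocyte_config())
prof = sq.steady_profile(membrane, geom, electrode, stim.amplitude)
print(sq.input_resistance(prof) / 1e6)   # 498.67 (MOhm)
```

Other CLI verbs: `sphereq steady`, `sphereq dynamics` (trace CSVs for any
YAML config; see `examples/adipocyte.yaml`), `sphereq clamp`
(voltage-clamp distortion sweeps plus the sphere↔cable matching fit) and
`sphereq figure {2a,2b,3a,3b,3c,4a,4b,4c}` for the canonical figure data.

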