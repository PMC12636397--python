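# hdcoop

Analysis toolkit for **cooperative DNA binding by Paired-like homeodomain
transcription factors** on palindromic P3 sites (TAAT–NNN–ATTA).

Homeodomains (HDs) are ~60-residue helix-turn-helix DNA-binding domains
that mostly recognize very similar TAAT monomer sites. Some members of the
Paired-like subfamily gain specificity by binding P3 sites as cooperative
homodimers, while the related ANTP subfamily cannot. `hdcoop` is for
biochemists and computational biologists who quantify that cooperativity
from gel-shift (EMSA) band intensities, map the sequence constraints that
permit it, classify homeodomains against position-specific cooperativity
rules, predict the consequences of missense variants, and analyze the
helix-packing geometry behind it.

## The core statistic

An EMSA lane resolves free probe *D*, the monomer complex *PD*, and the
dimer complex *P₂D*. The cooperativity factor is

$$\tau = \frac{4\,[P_2D]\,[D]}{[PD]^2}$$

τ = 1 is independent filling of the two half-sites, τ > 1 cooperative
binding (the first bound protein recruits the second), τ < 1
anti-cooperative. τ is the ratio of the two stepwise dissociation
constants (4·K_d1/K_d2) and is invariant to lane-wide exposure scaling.
Lanes qualify for aggregation only when more than 5% of the probe is
bound. Free-probe depletion (percent of probe in any bound state) tracks
overall affinity independent of dimerization.

Around τ, the package provides:

- **`hdcoop.emsa`** — per-lane τ and depletion, the >5% inclusion rule,
  replicate aggregation, and the standard comparison statistics
  (Levene-gated Student/Welch t-tests, one-/two-way ANOVA, Holm).
- **`hdcoop.constraints`** — positional residue profiles, sequence-logo
  information content (bits), the Paired-like-minus-ANTP differential bit
  map, one-hot Euclidean distances and complete-linkage clustering.
- **`hdcoop.rules`** — an 11-rule position-specific classifier of P3-site
  cooperativity (8 critical rules, 3 contributory), family censuses, and
  minimum-substitution counts.
- **`hdcoop.variants`** — consequence prediction for HD missense variants:
  cooperativity-decreasing, cooperativity-increasing, DNA-binding, or
  indeterminate, with a full evidence trail.
- **`hdcoop.geometry`** — Cα distance matrices from PDB/mmCIF, inter-helix
  spacing comparisons, Kabsch superposition and spacing grafts, and
  Shrake–Rupley SASA steric overlap.
- **`hdcoop.simulate`** — a mass-action equilibrium lane generator (the
  exact generative inverse of τ), profile-based sequence family sampling,
  and ideal-helix fixtures, so every stage runs without external data.

## Worked example

```python
from hdcoop import BindingModelConfig, simulate_lanes, summarize_group, tau_from_lane

cfg = BindingModelConfig(tau_true=100.0, kd_site=200.0, noise_cv=0.10, seed=7)
lanes = simulate_lanes(cfg)          # 4 concentrations x 3 replicates, 34 nM probe
est = tau_from_lane(lanes[0])
summary = summarize_group(lanes)
```

Running `python examples/01_tau_from_simulated_lanes.py` prints:

```
[P]=   25 nM  rep 1:  tau =    91.7  bound =  25.6%  included = True
[P]=   25 nM  rep 2:  tau =    90.8  bound =  25.9%  included = True
[P]=   25 nM  rep 3:  tau =    73.3  bound =  25.8%  included = True
[P]=   50 nM  rep 1:  tau =    88.3  bound =  53.4%  included = True

mean tau = 95.9 +/- 21.1 over 12 included lanes (truth: 100)
```

Each lane's band fractions give a τ estimate; with 10% multiplicative band
noise the 12-lane mean recovers the generative τ = 100 within a few
percent. The other scripts in `examples/` walk through constraint maps,
the Engrailed rule census (4 critical conflicts ⇒ 4 substitutions minimum
to permit cooperativity), variant annotation (R44Q vs R44G at the same
position diverge into cooperativity vs binding calls), and helix geometry.

A thin CLI mirrors the library: `hdcoop simulate|tau|constraints|rules|`
`variants|geometry`, each run writing its tables plus a `provenance.json`.

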