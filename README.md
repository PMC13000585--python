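# phenoxscreen

Screening substituted phenoxyl radicals for stability against reverse
hydrogen transfer.

Phenolic antioxidants protect hydrocarbons (lubricant base oils in
particular) by donating their hydroxyl hydrogen to peroxyl radicals.
The resulting phenoxyl radical must itself be stable: if it re-abstracts
a hydrogen from a surrounding hydroperoxide (ROOH), the protection is
undone. This package implements the computational side of that screen
for single-ring phenoxyl radicals carrying substituents from
{H, Me, OMe, tBu, COOH} at ring positions 2–6:

1. **Candidate library** — all 5⁵ substituent assignments are reduced to
   1625 distinct patterns under the ring mirror symmetry (2↔6, 3↔5;
   count = (5⁵+5³)/2 by Burnside's lemma), then filtered by four
   structural rules (≤2 tBu and ≤2 COOH; no ring-adjacent tBu–tBu or
   tBu–COOH; not tBu and COOH together on the two ortho positions; ≤4
   substituents) to a screened pool of **718 radicals**, serialized with
   RDKit-canonical SMILES and molecular masses.
2. **Descriptors** — per candidate: the diffusion coefficient *D* from
   the mean squared displacement via the Einstein relation
   (MSD slope = 6 *D* in 3-D); the H-bond protection probability
   *p*<sub>HB</sub>, the fraction of frames in which the phenoxyl oxygen
   accepts ≥1 hydrogen bond (donor–acceptor < 3 Å, donor–H–acceptor
   > 150°); and the percent buried volume %*V*<sub>bur</sub> of a 3.5 Å
   probe sphere around the phenoxyl oxygen, plus steric maps viewed
   along the C–O axis.
3. **Kinetics** — hydrogen-transfer events fire when a hydroperoxide
   hydrogen comes within 0.9 Å of a phenoxyl oxygen; cumulative counts
   averaged over realizations are fitted with
   N(t) = N<sub>∞</sub>(1 − e<sup>−kt</sup>), and the effective rate
   constant *k* (ns⁻¹) is the stability metric — lower *k*, more stable.
4. **Regression** — z-scored descriptors enter the multivariate model
   k̂ = β₀ + β₁·x_D + β₂·x_HB + β₃·x_BV, used to interpret which
   physical factor drives stability and to rank candidates.

Reactive molecular-dynamics trajectories are not part of the package;
instead a synthetic-data module generates every input the simulations
would produce — Brownian trajectories, H-bond scenes, packed mixtures,
and event series — with *planted* ground truth, so each stage is
validated as a recovery experiment (defaults: 100 radicals + 125
hydroperoxides per box, frames every 4 ps over 2 ns = 500 frames, three
realizations).

## Worked example

```sh
python analysis/01_build_library.py
python analysis/02_validate_recovery.py
python analysis/03_screen.py
python analysis/04_summarize_and_rank.py
```

`01` prints the library counts and writes `results/candidates.csv`:

```
distinct substitution patterns (mirror-canonical): 1625
Burnside cross-check (5^5 + 5^3)/2 = 1625
candidates surviving structural filters: 718
molecular mass range: 93.11 - 279.36 g/mol (median 207.25)
```

`02` validates every stage against planted truth (worst relative error
2.4% across diffusivity, H-bond probability, buried volume, and rate
recovery). `03` screens 24 candidates end to end:

```
screened 24 candidates (24 converged fits)
Spearman(planted k, recovered k) = 0.982
recovered k range: 2.66 - 14.40 /ns
```

`04` reports the fitted standardized coefficients, the stability
ranking (COOH-bearing candidates, whose carboxyl O–H protects the
phenoxyl oxygen, come out most stable), and the ortho steric-map table —
molecule-only buried volume rising monotonically from H/H (25.2%) to
tBu/tBu (52.0%), the expected shielding order for bulky ortho groups.

The CLI exposes the same stages (`phenoxscreen run-all --seed 7
--outdir run --subset 10`, plus `generate`/`synth`/`describe`/`fit`/
`regress`/`summarize`).

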