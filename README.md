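# cectrack

Tracking the **center of excess charge** (CEC) of a hydrated excess proton in
molecular dynamics trajectories, and biasing proton dissociation along it.

Grotthuss shuttling constantly rewires covalent and hydrogen bonds, so no
single hydrogen atom *is* "the proton": the net positive charge defect is
delocalized over several solvation shells and its carrier identity changes
from step to step. Analyses of proton solvation and transport — and any
enhanced-sampling simulation of proton dissociation from a weak acid — need a
smooth, differentiable position for that defect. `cectrack` computes one for
stored AIMD/QM-MM frames (XYZ trajectories, PDB snapshots), together with its
downstream uses: the excess-charge IR spectrum, a proton-dissociation
collective variable with analytic gradients, well-tempered metadynamics
utilities, and the calibration of the underlying charge-transfer model.

## The model

Each **diabatic state** |i⟩ is a bonding topology naming the one protonated
species (hydronium or neutral acid). Its center of charge uses fixed
per-atom *excess* charges q_I^i that sum to +1 e:

    COC_i = Σ_I q_I^i r_I / Σ_I q_I^i

States are enumerated breadth-first from the realized topology, transferring
a proton along each hydrogen bond (shared-H⋯acceptor-O ≤ 2.5 Å) through up
to three solvation shells — 20–30 states in bulk water. A hop's weight
factor is an exponential in the proton-transfer coordinate
δ = |r_H − r_D| − |r_H − r_A|:

    f_CT(δ) = exp(k (δ − δ₀))

with (k, δ₀) fitted to constrained-DFT charge-transfer data
(hydronium–water BLYP: k = 4.234 Å⁻¹, δ₀ = 0; ωB97X: k = 4.898 Å⁻¹;
Glu–water BLYP: k = 2.946 Å⁻¹, δ₀ = 0.5361 Å). State populations are path
products of f_CT normalized to Σ c_i² = 1, and

    r_CEC = Σ_i c_i² COC_i ,

equivalently the dipole of the per-atom excess charges Σ_i c_i² q_I^i. The
proton-dissociation CV is the smooth minimum distance to the two carboxyl
oxygens, ξ = softmin_κ(|r_CEC − r_O1|, |r_CEC − r_O2|) with κ = 40 Å⁻¹, and
the excess-charge IR spectrum is the Fourier transform of the CEC velocity
autocorrelation function.

## Worked example

The gas-phase Zundel scan moves the shared proton from donor-bound
(r_OH = 0.9 Å) to the O–O midpoint of a 2.6 Å pair:

```python
import numpy as np
import cectrack as ct
from cectrack.cec_core import cec_for_frame

scan = ct.make_zundel_scan(r_oo=2.6, n_frames=6)
print("r_OH    delta    c1^2    cec_x")
for fr in scan:
    res, states = cec_for_frame(fr)
    r_oh = np.linalg.norm(fr.positions[1] - fr.positions[0])
    delta = r_oh - np.linalg.norm(fr.positions[1] - fr.positions[4])
    print(f"{r_oh:.3f}  {delta:+.3f}   {res.weights[0]:.4f}  {res.cec[0]:.4f}")
```

prints

```
r_OH    delta    c1^2    cec_x
0.900  -0.800   0.9673  0.0958
0.980  -0.640   0.9376  0.1845
1.060  -0.480   0.8841  0.3298
1.140  -0.320   0.7949  0.5605
1.220  -0.160   0.6632  0.8928
1.300  +0.000   0.5000  1.3000
```

With the proton bound to the donor (δ = −0.8 Å) 97% of the charge stays on
the donor-side state and the CEC sits just off the donor oxygen; at equal
sharing the populations are exactly ½/½ and the CEC lies on the O–O
bisecting plane (x = 1.3 Å). The CEC moves continuously — no
identity-switch jumps — which is what makes it biasable.

The same machinery runs from the shell:

```
cectrack cec --trajectory traj.xyz --out-prefix out/run     # CEC track
cectrack spectrum --track out/run_track.csv --window-cm 33  # IR spectrum
cectrack fit --in table.csv --pair-kind glu-water           # (k, delta0) fit
cectrack metad-demo --barrier 3.0 --seed 1                  # sampling demo
```

Every command accepts `--config config.yaml` (stages, input files, acid
group declaration, charge tables) and `--seed`; each run writes a JSON
manifest, and outputs are bit-for-bit reproducible for a fixed config and
seed. Excess-charge tables and (k, δ₀) parameter files are plain JSON and
fully user-overridable; the shipped charge values are documented stand-ins
(see `docs/methods.md`).

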