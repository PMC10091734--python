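# teangio

Tools for designing and simulating **time-encoded pseudo-continuous ASL
(PCASL) dynamic angiography** protocols, and for reconstructing and
quantifying the resulting radial MRI acquisitions.

Dynamic ASL angiograms follow a bolus of magnetically labeled blood through
the arteries with a Look-Locker (LL) readout. Because every readout
excitation attenuates the remaining label, a long readout forces small flip
angles and low SNR. Hadamard time-encoding splits the PCASL preparation
into blocks whose label/control states follow the rows of a Hadamard
matrix; decoding the acquisitions recovers one control−label difference per
block, so part of the temporal information moves from the readout into the
preparation and the readout can be three times shorter — allowing larger
flip angles and roughly double the SNR. This package implements the full
method stack for comparing a conventional nine-frame sequential LL protocol
("Seq-LL", 108 excitations) with a 4×3 time-encoded protocol ("TEnc-LL",
36 excitations) that decodes to the same nine timepoints at 120 ms
resolution. It is aimed at ASL sequence developers and reproducibility-minded
MR physicists.

## What is inside

| Module | Contents |
|---|---|
| `teangio.protocol` | protocol presets, Hadamard encoding/decoding, effective timepoints, labeling-efficiency and transit-time utilities |
| `teangio.flip_angles` | constant (CFA) and variable (VFA) flip-angle design for SPGR LL readouts |
| `teangio.signal_model` | gamma-dispersed bolus signal model with RF attenuation and T1 decay |
| `teangio.bgs` | background-suppression inversion timing and null-time optimization |
| `teangio.phantom` | synthetic dynamic vessel phantom and multi-coil radial k-space generator |
| `teangio.recon` | phase correction, density compensation, Kaiser–Bessel gridding, adaptive-combine coil maps, Roemer combination, decoding |
| `teangio.quantify` | vessel masking, Rayleigh background-noise estimation, SNR, paired statistics |

The core design results, in the field's standard notation: the SPGR signal
acquired at excitation *n* is `sin θ(n) · Π_{m<n} cos θ(m)`. Maximizing the
last-excitation signal gives the optimal CFA `θ = arctan(1/√(N−1))`, and
the backward recursion `θ(n) = arctan(sin θ(n+1))` yields a VFA ramp with
perfectly constant acquired signal. The realistic bolus model is

```
S(t) = A · atten(t) · s^(1+p·s)/Γ(1+p·s) · ∫ e^(−s·t′) t′^(p·s) e^(−(Δt+t′)/T1) dt′
```

with the integral over the labeling window, a gamma dispersion kernel of
sharpness `s` and time-to-peak `p`, bolus arrival `Δt`, and blood `T1`.
Background suppression places two inversion pulses during labeling so that
tissue of a target T1 is nulled near the readout; a grid search over the
null time minimizes the worst acquired tissue signal `max |Mz(n)·sin θ(n)|`.

## Worked example

```python
>>> import numpy as np, teangio as tg
>>> np.degrees(tg.optimal_cfa(108)), np.degrees(tg.optimal_cfa(36))
(5.521832763483942, 9.594068226860461)
>>> np.degrees(tg.vfa_schedule(108, np.radians(30)).angles[0])
5.446473584743883
>>> tg.compare_dispersion_protocols()
                 no_dispersion  moderate_dispersion
tenc_vs_seq_cfa             70                   84
tenc_vs_seq_vfa             69                   69
vfa_vs_cfa_seq              22                   33
vfa_vs_cfa_tenc             22                   22
```

The optimal CFAs are 5.5° (Seq-LL) and 9.6° (TEnc-LL); a VFA ramp ending at
30° starts at 5.45° and 9.21°. The table shows mean decoded-signal
improvements in percent at the reconstructed 120 ms resolution: with a
moderately dispersed bolus (s = 10 s⁻¹, p = 0.1 s, arrival 650 ms) the
time-encoded protocol gains 84% (CFA) or 69% (VFA) over the sequential one,
and the VFA ramp adds 33%/22% over the CFA within each protocol.

Background-suppression optimization, from the command line:

```
$ teangio optimize-bgs --protocol seq-ll
{
  "t_null_norf_ms": -87,
  "objective": 0.10818005060569184,
  "t_bgs1_s": 0.12645243729950695,
  "t_bgs2_s": 0.3495184500667655,
  "ti_s": 0.449
}
```

i.e. the best achievable tissue nulling for the Seq-LL VFA readout occurs
87 ms *after* the first excitation (−217 ms for TEnc-LL), with both
inversion pulses placed inside the labeling period.

A complete synthetic experiment — phantom, multi-coil radial k-space,
reconstruction, SNR report:

```
teangio synth --protocol tenc-ll --scheme vfa --matrix 96 --segments 13 \
        --noise-sd 0.05 --out k.h5
teangio recon --kspace k.h5 --out series.nii.gz --qc-montage qc.png
teangio snr --kspace k.h5 --out snr.json --mask-out mask.nii.gz
```

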