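# radarid

Contactless identity recognition from millimeter-wave FMCW radar vital signs.

A 77 GHz FMCW radar pointed at a seated person measures chest displacement with
sub-wavelength precision: the slow-time phase of the intermediate-frequency
(IF) signal at the thoracic range bin is `4*pi*(R0 + d(t))/lambda_c`, where
`d(t)` is the mm-scale chest motion driven by respiration (0.15–0.4 Hz) and
heartbeat (0.8–1.5 Hz).  Because breathing depth and waveform shape, cardiac
harmonic structure, and their rates differ between people, these signals act
as a biometric.  `radarid` implements the full pipeline:

1. **Simulator** (`radarid.simulate`) — physics-based synthetic IF data cubes
   (frames × chirps × 256 ADC samples) for labeled subject cohorts, with DC
   bias, static reflectors, wandering dynamic clutter, oscillator phase noise
   and thermal noise.
2. **Range processing** (`radarid.ranging`) — per-frame range FFT into a
   range/slow-time matrix, DC removal (row means), adaptive background
   subtraction `B[n] = 0.9 B[n-1] + 0.1 Q[n]` for static clutter, rank-1 SVD
   truncation for dynamic clutter, and thorax localization
   `argmax_m sum_n |Q[m, n]|`.
3. **Phase extraction** (`radarid.phase`) — four-quadrant angle of the K = 7
   bins around the thorax, per-row unwrapping, first-order differencing.
4. **Modal separation** (`radarid.modal`) — zero-phase 2nd-order Butterworth
   bandpass into respiration (0.15–0.4 Hz) and heartbeat (0.8–1.5 Hz)
   channels, with the unfiltered differenced phase kept as a third modality;
   z-scored sliding windows (10.24 s default).
5. **Fusion network** (`radarid.network`, on the numpy autograd core in
   `radarid.nn`) — three branch ResNets (one per modality), CBAM-style
   channel + spatial attention fusion
   `F'' = M_S ⊙ (M_C ⊙ (F1 + F2 + F3))`, scaled dot-product temporal
   self-attention `softmax(Q K^T / sqrt(d_k)) V`, a 128-d embedding and a
   softmax identity classifier.
6. **Experiment harness** (`radarid.experiment`) — record-level stratified
   7:3 split, Adam/cross-entropy training, window-level accuracy with
   row-normalized confusion matrices, ablation drivers (distance units,
   window length, residual blocks, fusion scheme) and unimodal baselines.

## Worked example

```python
import radarid as ri

pipe = ri.PipelineConfig(n_subjects=5, records_per_subject=20,
                         radar=ri.RadarConfig(n_frames=1000),
                         window_length=512, window_step=64, master_seed=0)
table, reports = ri.run_modality_comparison(pipe, train_cfg=ri.TrainConfig(epochs=20))
print(table.to_string(index=False))
```

prints (seed 0, ~9 minutes on one CPU):

```
model_input  accuracy
respiration  0.445833
  heartbeat  0.875000
      phase  0.791667
 multimodal  0.920833
```

Each row is the held-out window accuracy of one model on the same cohort and
record split: the three single-branch unimodal baselines, then the
three-branch fusion network.  92% of the 240 held-out test windows (6 unseen
records per subject) are attributed to the correct one of five synthetic
subjects, and fusing the modalities beats every single modality — respiration
alone is weakest because breathing windows carry few cycles and the cohort's
breath rates overlap.  `reports["multimodal"].confusion` holds the
row-normalized confusion matrix.

The same experiment is available from the shell:

```sh
radarid -v pipeline --subjects 5 --records 20 --frames 1000 --epochs 20 \
        --seed 0 --out runs/demo
radarid -v ablate --axis distance_units --values 3,5,7,9 --out runs/du.csv \
        --subjects 3 --records 6 --frames 750 --epochs 5
```

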