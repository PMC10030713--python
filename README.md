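# ecgtopo

Topological quality assessment of ECG signals. Ten-second ECG segments are
delay-embedded into point clouds, summarized by persistent homology — H0/H1
of a Vietoris-Rips filtration of the cloud, or 0-dimensional sublevel-set
persistence of the raw trace — rendered as fixed-size barcode/diagram images,
and classified as *acceptable* vs *unacceptable* under 10-fold
cross-validation. A synthetic data factory generates clean P-QRS-T waveforms
and four contaminant classes (baseline wander, electrode motion, muscle
artifact, white Gaussian) mixed at a controlled SNR (default −10 dB), so the
full pipeline runs without any downloads.

## Layout

| module | role |
|---|---|
| `ecgtopo.ecg_io` | WFDB (format-16) / CSV record I/O, min-max normalization, lead splitting, empty-lead detection |
| `ecgtopo.synthetic_data` | clean ECG + noise generators, SNR mixing, noise allocation, dataset construction |
| `ecgtopo.embedding` | sliding-window delay embedding, dimension arithmetic, 12-lead stacking |
| `ecgtopo.persistence` | VR filtration, boundary-matrix reduction, MST fast path for H0, sublevel-set sweep |
| `ecgtopo.rendering` | deterministic 224×224×3 barcode/diagram rasterization, PNG I/O |
| `ecgtopo.classify_eval` | confusion matrix, Se/Sp/F1/Acc/mAcc, stratified k-fold CV, pluggable classifier backends |
| `ecgtopo.cli` | `ecgtopo` command-line front-end and the end-to-end pipeline |

Classifier backends: `baseline_cnn` (fixed seeded random convolution
features + logistic head; the CPU-friendly default), `linear_pixels`
(logistic regression on downsampled pixels) and `googlenet_transfer`
(optional; requires torch/torchvision with pretrained weights).

## CLI

```sh
# end-to-end synthetic experiment (simulate -> persistence -> render -> 10-fold CV)
ecgtopo run-all --filtration sls --n-acceptable 200 --n-corrupt 200 --seed 1 --work-dir run/

# individual stages
ecgtopo simulate --out-dir sim/ --count 10 --seed 1
ecgtopo build-dataset --clean-dir sim/ --out-dir ds/ --snr-db -10 --weights bw=2,em=2,ma=2,gaussian=1
ecgtopo embed --record ds/clean00000.csv --window-seconds 0.1 --out cloud.csv
ecgtopo persist --record ds/clean00000.csv --filtration sls --out diag.csv
ecgtopo render --diagram diag.csv --kind barcode --out diag.png
ecgtopo evaluate --images-dir images/ --backend baseline_cnn --k 10 --out cv.json
```

`run-all` also accepts a YAML config (`--config run.yaml`) with any
`RunConfig` field; flags override the file. Exit codes: 0 success, 2 config
error, 3 data error.

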