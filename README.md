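# ivhypoxia

Quantitative analysis of intravital tumor-hypoxia imaging: linear
spectral unmixing of multichannel fluorescence images, tumor-ROI and
vessel segmentation with vascular-distance hypoxia gradients, FFT-based
collagen fiber orientation with an ellipse alignment score,
serial-section colocalization, and the shared statistics that tie the
stages together. A synthetic scene generator with known ground truth
(tumor blobs, tubular vessel networks, distance-driven reporter
gradients, oriented peritumoral fiber fields, spectral crosstalk and
noise) makes every stage verifiable without a microscope.

## Layout

| Module | Purpose |
| --- | --- |
| `ivhypoxia.synthetic_scenes` | Scenes, serial-section stain sets, decay time courses with ground truth |
| `ivhypoxia.spectral` | Coefficient-matrix estimation from controls; per-pixel least-squares unmixing |
| `ivhypoxia.roi_vasculature` | Tumor ROI, 100-µm expansion, SLIC+adaptive vessel segmentation, distance transform, 20-µm cell sampling |
| `ivhypoxia.collagen` | Interface tracing, 100-µm moving ROIs, FFT orientation, alignment score (1 − b/a)×100 |
| `ivhypoxia.exvivo_coloc` | Bicubic coarse downsampling, pairwise Pearson stain matrix, top-decile positive-stain fraction |
| `ivhypoxia.stats_report` | Pearson/Welch statistics, half-life fitting, study-level aggregation and report output |

## CLI

```bash
ivhypoxia simulate --seed 1 --size 512 --out scene.tif
ivhypoxia unmix --image scene.tif --matrix R.csv --out unmixed.tif
ivhypoxia quantify --image unmixed.tif --config cfg.yaml --out metrics/
ivhypoxia collagen --image unmixed.tif --tumor-mask tumor.tif --out rois.csv
ivhypoxia coloc --stains GFP gfp.tif --stains PIMO pimo.tif --factor 100 --out coloc/
ivhypoxia report --in metrics/ --out report/
```

Images are multi-page TIFFs with a JSON sidecar carrying channel names
and the physical pixel size; coefficient matrices are CSV with channel
headers and fluorophore index; masks are 8-bit TIFFs.

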