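# rnlpipe

A tested, reusable pipeline for animal-coloration conspicuousness analysis:
from raw reflectance spectra of prey (dorsal frog readings) and natural
substrates, through receptor-noise-limited visual models of three predator
types (a tetrachromatic UV-sensitive bird, a tetrachromatic lizard with
oil-droplet-filtered cones, and a dichromatic crab), to chromatic (ΔS) and
achromatic (ΔL) contrasts in JND units, exact perceptual-space coordinates,
and information-theoretic mixed-model inference (AICc ranking, Akaike
weights, model averaging, importance and strong-effect flags).

A synthetic-data generator reproduces the study layout (2 species x
red/green morphs over 9 localities, 8 males per locality, 4 dorsal reads per
frog, 3 substrate classes with 6 reads per object), so every stage is
testable without any external download.

## Modules

| module | purpose |
|---|---|
| `rnlpipe.spectra` | read (wide/long CSV), trim to 300–700 nm, clip negatives, LOESS-smooth (span 0.2), interpolate to a 1-nm grid, average replicates |
| `rnlpipe.visual` | A1 pigment templates, logistic oil-droplet filtering, the three predator systems, noise rule `e_i = w_ref * sqrt(eta_ref/eta_i)`, bundled forest-shade illuminant, YAML (de)serialization |
| `rnlpipe.contrasts` | quantum catches, general-n receptor-noise-limited ΔS, Weber-scaled ΔL, the frog x predator x substrate contrast table, MAD outlier flagging |
| `rnlpipe.space` | exact whitening-based perceptual embeddings (pairwise distances equal ΔS to 1e-6) and the dichromat chromaticity/luminance plane |
| `rnlpipe.mmi` | candidate enumeration under marginality (113 models over 4 factors), ML random-intercept mixed models with profiled deviance, AICc, weights, evidence ratios, 95% confidence sets, conditional model averaging |
| `rnlpipe.simulate` | parametric spectra (logistic red edge / Gaussian green band), substrate shapes, and balanced LMM-structured contrast tables for recovery tests |
| `rnlpipe.cli` | `rnlpipe` command: `simulate`, `preprocess`, `contrasts`, `space`, `stats`, `run-all` |

## CLI

```sh
# write a synthetic study (spectra + design table + illuminant) to CSVs
rnlpipe simulate --seed 1 --out study/

# full pipeline on synthetic data
rnlpipe run-all --simulate --seed 1 --out results/run1

# full pipeline on real data, via a YAML config
rnlpipe run-all --config config.yaml

# stats stage alone, from an existing contrast table
rnlpipe stats --contrasts results/run1/contrasts.csv --response deltaS --out results/stats
```

`run-all` writes: cleaned spectra, the tidy contrast CSV (with outlier
flags), perceptual coordinates per predator, model-averaged estimate tables
for ΔS and ΔL, the AICc model ranking, and a manifest (resolved config +
seed + version) for reproducibility. Reruns with the same config are
byte-identical.

A config YAML may set any `PipelineConfig` field, e.g.:

```yaml
simulate: true
seed: 1
span: 0.2
confidence_mass: 0.95
importance_threshold: 0.80
candidate_cap: 100
```

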