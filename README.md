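# benthicflux

Estimation of benthic solute fluxes for sediment biogeochemistry studies:

* **incubation** — effluxes from sequentially sampled closed-core incubations
  with partial overlying-water replacement (interval fluxes, cumulative
  fluxes, replicate statistics, sulfide-onset detection),
* **profile_flux** — tortuosity-corrected Fickian diffusive fluxes from
  pore-water depth profiles, subsurface-peak production partitioning, and
  microsensor feature extraction (oxygen penetration depth, sulfide
  appearance depth, pH extrema),
* **inventory** — solid-phase inventory integration and before/after change,
* **budget** — oxic-zone trapping/escape fluxes, mixed-layer dilution,
  sorption-capacity release, cumulative element ratios,
* **physchem** — diffusion coefficients in seawater (editable registry,
  viscosity-ratio salinity correction), tortuosity, porosity from water
  content,
* **synthetic** — scenario generator with exactly known truth for three
  seasonal regimes (`march`, `may`, `august`) of a seasonally hypoxic basin,
* **io / pipeline / cli** — delimited-text readers/writers, YAML config, and
  a `benthicflux` command-line pipeline.

Conventions: depth in m, positive downward, sediment-water interface at 0;
concentration mmol m⁻³ (= µM); flux mmol m⁻² d⁻¹, positive downward; depth
windows are half-open `[top, bottom)`.

## Command line

```sh
# generate a synthetic dataset with known truth
benthicflux simulate --preset march --seed 1 --out data/

# run the full pipeline (features -> fluxes -> inventories -> budgets)
benthicflux run --input-dir data/ --out results/

# individual stages
benthicflux features --profiles data/profiles.csv
benthicflux profile-flux --profiles data/profiles.csv --porosity 0.85
benthicflux incubation --file data/incubation.csv
benthicflux inventory --before data/solids_before.csv --after data/solids_after.csv
benthicflux budget --production 0.85 --upward-fraction 0.45 --trapped 0.3 \
    --cumulative 0.06 --cumulative 0.48 --height 15
```

`benthicflux run` accepts a YAML config (`--config`) covering detection
limits, gradient window size, the assumed arsenic species (`HAsO4--` by
default, switchable to `H2AsO4-`/`H3AsO3`), core area, solid density and the
mixed-layer height; all defaulted values are echoed to the log (stderr).

## Data formats

Comma-separated UTF-8 with a header row:

| file | columns |
| --- | --- |
| profiles | `core_id,campaign,species,depth_m,conc_uM` |
| incubation | `core_id,species,time_d,conc_uM,v_olw_L,v_repl_L,conc_repl_uM` |
| solids | `core_id,campaign,species,extraction,depth_top_m,depth_bot_m,conc_umol_g` |

The free-solution diffusivity registry
(`src/benthicflux/data/diffusion_coefficients.csv`) ships linear-in-
temperature constants and can be overridden per run (`registry_path`).
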