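"""YAML/JSON configuration loading for the pipeline CLI."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from .bands import Band, BandSet
from .pipeline import PipelineConfig
from .preprocess import PreprocessConfig
from .synthetic import CohortSpec, TopologySpec


def _topology_spec(d: dict[str, Any], n_sources: int) -> TopologySpec:
    d = dict(d)
    band = Band(d.pop("band_name", "band"),
                d.pop("low"), d.pop("high"))
    return TopologySpec(n_nodes=d.pop("n_nodes", n_sources), band=band, **d)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}

    cohort_d = dict(raw.get("cohort", {}))
    band_specs_d = cohort_d.pop("band_specs", None)
    overrides_d = cohort_d.pop("condition_overrides", None)
    cohort = CohortSpec(**cohort_d)
    n_sources = cohort.n_sources
    if band_specs_d is not None:
        cohort = CohortSpec(**{**cohort_d, "band_specs": {
            name: _topology_spec({**d, "band_name": name}, n_sources)
            for name, d in band_specs_d.items()}})
    if overrides_d is not None:
        base = cohort.resolved_band_specs()
        overrides = {}
        for cond, m in overrides_d.items():
            overrides[cond] = {}
            for name, d in m.items():
                merged = {**base[name].__dict__, **d}
                merged.pop("band", None)
                merged.setdefault("low", base[name].band.low)
                merged.setdefault("high", base[name].band.high)
                overrides[cond][name] = _topology_spec(
                    {**merged, "band_name": name}, n_sources)
        cohort = CohortSpec(**{**cohort_d,
                               "band_specs": cohort.band_specs,
                               "condition_overrides": overrides})

    pre_d = dict(raw.get("preprocess", {}))
    if "notch_freqs" in pre_d:
        pre_d["notch_freqs"] = tuple(pre_d["notch_freqs"])
    pre = PreprocessConfig(**pre_d)

    if "bands" in raw:
        bands = BandSet([Band(*b) for b in raw["bands"]])
    else:
        bands = BandSet.default()

    kwargs = {k: raw[k] for k in
              ("norm_scope", "metric_scope", "epoch_mode", "compute_power",
               "alpha", "outcomes") if k in raw}
    return PipelineConfig(cohort=cohort, preprocess=pre, bands=bands, **kwargs)
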