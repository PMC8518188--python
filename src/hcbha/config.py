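"""YAML configuration mapped onto the pipeline options.

The file uses dotted sections, e.g.::

    binning:
      cov_weight: 3.0
      min_bin_bases: 50000
    phasing:
      min_score: 3
    assembly:
      min_overlap: 500
    iterate:
      stop_threshold: 0.02
      max_iter: 11

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .iterate import PipelineOptions

_SECTION_KEYS = {
    "binning": {"min_bin_bases", "cov_weight", "linkage", "metric",
                "cut_mode"},
    "phasing": {"phasing_k", "phasing_w", "min_score", "tie_ratio"},
    "assembly": {"min_long_reads", "min_overlap", "min_chain_score",
                 "polish_rounds", "min_bridges"},
    "iterate": {"stop_threshold", "max_iter", "iter_long_bases",
                "iter_short_bases", "seed"},
}
# section-local aliases (config uses short names inside sections)
_ALIASES = {("phasing", "k"): "phasing_k", ("phasing", "w"): "phasing_w"}


def load_options(path) -> PipelineOptions:
    """Load PipelineOptions from a YAML config file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for section, entries in data.items():
        if section not in _SECTION_KEYS:
            raise KeyError(f"unknown config section {section!r}")
        for key, value in (entries or {}).items():
            key = _ALIASES.get((section, key), key)
            if key not in _SECTION_KEYS[section]:
                raise KeyError(f"unknown key {section}.{key}")
            kwargs[key] = value
    return PipelineOptions(**kwargs)
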