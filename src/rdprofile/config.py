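"""Run configuration: one YAML/JSON document describing a whole analysis.

Sections mirror the pipeline stages (domain, source, params, bounds,
observation, noise, optimizer, profiling) plus a top-level seed and output
directory.  Unknown keys are rejected so that typos fail loudly, and the
parsed configuration is echoed verbatim into every output artifact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .grid import DomainGrid
from .model import DEFAULT_KINETIC_BOUNDS, KINETIC_NAMES, ModelParameters
from .sources import (
    DEFAULT_BRANCH_POINT,
    DEFAULT_HALF_WIDTH,
    DEFAULT_STEM_BASE,
    DEFAULT_TIP_LEFT,
    DEFAULT_TIP_RIGHT,
    SourceMap,
    build_y_source,
)


def _check_keys(section: str, given: dict, allowed: set[str]):
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated configuration for simulate/fit/profile runs."""

    nx: int = 50
    stem_base: tuple = DEFAULT_STEM_BASE
    branch_point: tuple = DEFAULT_BRANCH_POINT
    tip_left: tuple = DEFAULT_TIP_LEFT
    tip_right: tuple = DEFAULT_TIP_RIGHT
    half_width: float = DEFAULT_HALF_WIDTH
    soft_edge: float | None = None
    params: dict = field(default_factory=lambda: {
        "D": 0.5, "alpha": 0.1, "k1": 5.0, "km1": 1.0, "gamma": 0.1,
        "b": 1e-4, "sigma2": 1e-4,
    })
    bounds: dict = field(default_factory=lambda: {
        name: list(DEFAULT_KINETIC_BOUNDS) for name in KINETIC_NAMES
    })
    rows: int = 10
    cols: int = 5
    times: tuple = tuple((k + 1) / 5 for k in range(5))
    sigma: float | None = None  # log-intensity std; overrides params.sigma2
    rtol: float = 1e-8
    atol: float = 1e-10
    n_starts: int = 10
    opt_method: str = "hybrid"
    opt_tol: float = 1e-9
    opt_max_iter: int = 500
    alpha: float = 0.98
    profile_parameters: tuple = KINETIC_NAMES
    init_step: float = 0.02
    stop_margin: float = 0.1
    seed: int = 1
    output_dir: str = "rdprofile_out"
    raw: dict = field(default_factory=dict, repr=False)

    _SECTIONS = {
        "domain": {"nx"},
        "source": {"stem_base", "branch_point", "tip_left", "tip_right",
                   "half_width", "soft_edge"},
        "params": {*KINETIC_NAMES, "b", "sigma2"},
        "bounds": set(KINETIC_NAMES),
        "observation": {"rows", "cols", "times"},
        "noise": {"sigma", "sigma2"},
        "solver": {"rtol", "atol"},
        "optimizer": {"n_starts", "method", "tol", "max_iter"},
        "profiling": {"alpha", "parameters", "init_step", "stop_margin"},
    }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        _check_keys("<top level>", doc, set(cls._SECTIONS) | {"seed", "output_dir"})
        cfg = cls(raw=doc)
        for section, allowed in cls._SECTIONS.items():
            sub = doc.get(section) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            _check_keys(section, sub, allowed)
        dom = doc.get("domain") or {}
        cfg.nx = int(dom.get("nx", cfg.nx))
        src = doc.get("source") or {}
        for key in ("stem_base", "branch_point", "tip_left", "tip_right"):
            if key in src:
                setattr(cfg, key, tuple(map(float, src[key])))
        cfg.half_width = float(src.get("half_width", cfg.half_width))
        if src.get("soft_edge") is not None:
            cfg.soft_edge = float(src["soft_edge"])
        cfg.params = {**cfg.params, **(doc.get("params") or {})}
        for name, pair in (doc.get("bounds") or {}).items():
            cfg.bounds[name] = [float(pair[0]), float(pair[1])]
        obs = doc.get("observation") or {}
        cfg.rows = int(obs.get("rows", cfg.rows))
        cfg.cols = int(obs.get("cols", cfg.cols))
        if "times" in obs:
            cfg.times = tuple(float(t) for t in obs["times"])
        noise = doc.get("noise") or {}
        if "sigma" in noise and "sigma2" in noise:
            raise ConfigError("give either noise.sigma or noise.sigma2, not both")
        if "sigma" in noise:
            cfg.params["sigma2"] = float(noise["sigma"]) ** 2
        if "sigma2" in noise:
            cfg.params["sigma2"] = float(noise["sigma2"])
        sol = doc.get("solver") or {}
        cfg.rtol = float(sol.get("rtol", cfg.rtol))
        cfg.atol = float(sol.get("atol", cfg.atol))
        opt = doc.get("optimizer") or {}
        cfg.n_starts = int(opt.get("n_starts", cfg.n_starts))
        cfg.opt_method = str(opt.get("method", cfg.opt_method))
        cfg.opt_tol = float(opt.get("tol", cfg.opt_tol))
        cfg.opt_max_iter = int(opt.get("max_iter", cfg.opt_max_iter))
        prof = doc.get("profiling") or {}
        cfg.alpha = float(prof.get("alpha", cfg.alpha))
        if "parameters" in prof:
            bad = set(prof["parameters"]) - set(KINETIC_NAMES)
            if bad:
                raise ConfigError(f"unknown profiling parameter(s) {sorted(bad)}")
            cfg.profile_parameters = tuple(prof["parameters"])
        cfg.init_step = float(prof.get("init_step", cfg.init_step))
        cfg.stop_margin = float(prof.get("stop_margin", cfg.stop_margin))
        cfg.seed = int(doc.get("seed", cfg.seed))
        cfg.output_dir = str(doc.get("output_dir", cfg.output_dir))
        return cfg

    # -- derived model objects ------------------------------------------------

    def grid(self) -> DomainGrid:
        return DomainGrid(nx=self.nx)

    def source(self, grid: DomainGrid | None = None) -> SourceMap:
        return build_y_source(
            grid or self.grid(),
            stem_base=self.stem_base,
            branch_point=self.branch_point,
            tip_left=self.tip_left,
            tip_right=self.tip_right,
            half_width=self.half_width,
            soft_edge=self.soft_edge,
        )

    def parameters(self) -> ModelParameters:
        bounds = tuple(tuple(self.bounds[name]) for name in KINETIC_NAMES)
        return ModelParameters(bounds=bounds, **self.params)

    def echo(self) -> dict:
        """The fields that define the run, for embedding in artifacts."""
        d = asdict(self)
        d.pop("raw", None)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON — a YAML subset) config file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    return RunConfig.from_dict(doc)
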