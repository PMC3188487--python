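"""Full-analysis orchestration and run configuration.

`run_full_analysis` chains structure reading, network construction, the
perturbation scan, hot-residue selection and pathway search, and writes the
χ profile (TSV), the pathway (JSON) and optionally a χ plot, each with a
provenance header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from . import __version__
from .pathway import (Pathway, build_overlap_graph, candidate_set,
                      dominant_direction, max_weight_pathway)
from .scan import ChiProfile, PerturbationResponseScanner, select_hot_residues
from .structures import CalphaModel, parse_pocket_spec, read_structure

__all__ = ["RunConfig", "RunResult", "run_full_analysis", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Parameters of a full run. Defaults are the method's canonical
    settings: γ_b = 1, c = 8, the 7-direction scan, χ threshold 1.0,
    overlap cutoff 0.98, window 3."""

    structure: str = ""
    chain: str | None = None
    pocket: str = ""
    gamma_bonded: float = 1.0
    nonbonded_numerator: float = 8.0
    pinv_tolerance: float = 1e-8
    cutoff: float | None = None
    n_random_directions: int | None = None
    magnitude_mode: str = "squared"
    combine: str = "max"
    threshold: float = 1.0
    overlap_cutoff: float = 0.98
    window: int = 3
    drop_residues: str = ""  # e.g. "394-399" to truncate before ENM construction
    seed: int = 0
    chi_out: str | None = None
    pathway_out: str | None = None
    plot_out: str | None = None
    log_level: str = "INFO"


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize as a flat key=value file (None written as empty)."""
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        lines.append(f"{f.name}={'' if v is None else v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat key=value file; keyword arguments take precedence."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    kwargs = {}
    for f in fields(RunConfig):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if val == "":
            kwargs[f.name] = None if "None" in str(f.type) or f.name in (
                "chain", "cutoff", "n_random_directions", "chi_out",
                "pathway_out", "plot_out") else ""
        elif f.type in ("float", "float | None"):
            kwargs[f.name] = float(val)
        elif f.type in ("int", "int | None"):
            kwargs[f.name] = int(val)
        else:
            kwargs[f.name] = val
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    model: CalphaModel
    scanner: PerturbationResponseScanner
    chi: ChiProfile
    hot: list[tuple]
    pathway: Pathway
    provenance: dict = field(default_factory=dict)


def _provenance(cfg: RunConfig) -> dict:
    prov = {"tool": "prscan", "version": __version__, "parameters": asdict(cfg)}
    p = Path(cfg.structure)
    if cfg.structure and p.exists():
        prov["input_sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
    return prov


def run_full_analysis(cfg: RunConfig, model: CalphaModel | None = None) -> RunResult:
    """Execute the whole procedure: structure → network → scan → χ →
    hot residues → window expansion → overlap graph → max-weight pathway.

    ``model`` may be given directly (e.g. a synthetic fixture); otherwise
    ``cfg.structure`` is read from disk.
    """
    if model is None:
        if not cfg.structure:
            raise ValueError("no structure given (cfg.structure or model argument)")
        model = read_structure(cfg.structure, chain=cfg.chain)
    if cfg.drop_residues:
        drop = parse_pocket_spec(cfg.drop_residues, model).residue_selectors
        model = model.drop_residues(drop)
    scanner = PerturbationResponseScanner(
        gamma_bonded=cfg.gamma_bonded,
        nonbonded_numerator=cfg.nonbonded_numerator,
        cutoff=cfg.cutoff,
        pinv_tolerance=cfg.pinv_tolerance,
        magnitude_mode=cfg.magnitude_mode,
        combine=cfg.combine,
        threshold=cfg.threshold,
        n_random_directions=cfg.n_random_directions,
        random_state=cfg.seed,
    ).fit(model)
    pocket = parse_pocket_spec(cfg.pocket, model)
    chi = scanner.chi_profile(pocket)
    hot = select_hot_residues(chi, cfg.threshold)
    candidates = candidate_set(hot, model, window=cfg.window)
    directional = dominant_direction(scanner.compliance_, candidates[0], pocket) \
        if candidates else None
    if candidates:
        # directional entries for every candidate, one container
        for k in candidates[1:]:
            directional.entries.update(
                dominant_direction(scanner.compliance_, k, pocket).entries)
        graph = build_overlap_graph(candidates, directional,
                                    cutoff=cfg.overlap_cutoff, model=model)
        pw = max_weight_pathway(graph)
    else:
        pw = Pathway(residues=[], indices=[], edge_overlaps=[], total_weight=0.0,
                     warning="no residues above the χ threshold")
    result = RunResult(model=model, scanner=scanner, chi=chi, hot=hot,
                       pathway=pw, provenance=_provenance(cfg))
    _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: RunConfig, res: RunResult) -> None:
    header = "# " + json.dumps(res.provenance["parameters"], sort_keys=True)
    if cfg.chi_out:
        df = res.chi.as_dataframe()
        with open(cfg.chi_out, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    if cfg.pathway_out:
        payload = {
            "provenance": res.provenance,
            "residues": [list(r) for r in res.pathway.residues],
            "labels": res.pathway.labels(res.model),
            "edge_overlaps": res.pathway.edge_overlaps,
            "total_weight": res.pathway.total_weight,
            "warning": res.pathway.warning,
        }
        Path(cfg.pathway_out).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if cfg.plot_out:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nums = res.model.author_numbers()
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(nums, res.chi.chi, lw=1.2)
        ax.axhline(res.chi.threshold, color="r", ls="--", lw=0.8)
        ax.set_xlabel("residue (author numbering)")
        ax.set_ylabel(r"allosteric response ratio $\chi$")
        ax.set_title(res.model.source_label)
        fig.tight_layout()
        fig.savefig(cfg.plot_out, dpi=150)
        plt.close(fig)
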