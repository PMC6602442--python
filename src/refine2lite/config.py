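"""Default parameters for the refinement protocol.

All numbers here are the package's contract: energy weights, restraint
settings, relaxation step counts (the three relaxation contexts keep the
14.4 : 3.0 : 1.2 ratio of the long / standard / post-loop schedules),
operator amplitudes, and the pool schedule. Every key can be overridden
from a YAML config file via :func:`load_config`.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

#: Ideal backbone covalent geometry (Angstrom / degrees), Engh-Huber-like.
IDEAL_GEOMETRY = {
    "bond_n_ca": 1.458,
    "bond_ca_c": 1.525,
    "bond_c_n": 1.329,
    "bond_c_o": 1.231,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
    "angle_ca_c_o": 120.8,
    "bond_ca_cb": 1.530,
    "bond_cb_cg": 1.520,
    "bond_cg_cd": 1.520,
    "angle_sidechain": 111.0,
}

#: Van der Waals radii (Angstrom) used by the clash score and steric term.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Residue-count cap mirrored from the server-style input contract.
MAX_RESIDUES = 300

#: Chain-intactness threshold on consecutive C-N distance (Angstrom).
CHAIN_BREAK_CN = 2.0

DEFAULTS: dict[str, Any] = {
    # --- energy term weights (dimensionless multipliers) ---
    "weights": {
        "steric": 1.0,
        "hbond": 0.5,
        "torsion_stat": 0.2,
        "compactness": 0.05,
        "restraint": 1.0,
    },
    # --- restraints ---
    "restraint_form": "lorentzian",        # default mode
    "neglect_fraction": 0.10,              # worst 10% neglected per class
    "conservative_form": "harmonic",       # Conservative mode
    "conservative_neglect_fraction": 0.05,
    "lorentzian_softness": 3.0,            # c in w*d^2/(d^2+c^2), Angstrom
    "restraint_weight_anchor": 1.0,        # per-restraint weights w
    "restraint_weight_ca_pair": 0.3,
    "restraint_weight_no_pair": 0.3,
    "ca_pair_cutoff": 12.0,                # Angstrom, |i-j| >= 4
    "ca_pair_min_sep": 4,
    "no_pair_cutoff": 3.5,                 # Angstrom
    # --- relaxation schedules; steps keep the 14.4 : 3.0 : 1.2 ratio ---
    "relax_steps_long": 1200,
    "relax_steps_standard": 250,
    "relax_steps_short": 100,
    "sidechain_repack_every": 100,         # mirrors repacking every 1.2 ps
    "noise_amplitude": 0.08,               # Angstrom, noisy-minimize kicks
    # --- error estimation ---
    "rmsf_runs": 24,
    "error_coeffs": {"intercept": 0.0, "w_rmsf": 1.0, "w_frag": 0.05, "w_msa": 0.3},
    "ulr_min_len": 3,
    "ulr_merge_gap": 1,
    "ulr_threshold_sd": 1.0,               # threshold = mean + k*SD
    "fragment_window": 7,
    # --- threading ---
    "tm_filter_threshold": 0.5,
    "min_coverage": 0.4,
    "patch_window_min": 5,
    "patch_window_max": 15,
    # --- operators ---
    "enm_cutoff": 10.0,                    # Angstrom
    "enm_n_low_modes": 10,
    "nma_amplitude": 1.0,                  # Angstrom RMS CA displacement
    "ss_max_rotation": 10.0,               # degrees
    "ss_max_translation": 1.0,             # Angstrom
    "loop_mutate_sigma": 30.0,             # degrees
    "tlc_max_attempts": 20,
    "operator_weights": {
        "fragment_assembly": 1.0,
        "loop_modelling": 1.0,
        "sidechain_perturbation": 1.0,
        "normal_mode_perturbation": 1.0,
        "hybridization": 1.0,
        "secondary_structure_perturbation": 1.0,
    },
    # --- refinement loop ---
    "pool_capacity": 48,
    "trials_per_member": 10,
    "cycles": 5,
    "closeness_start": 0.5,                # Angstrom CA-RMSD
    "closeness_end": 2.0,
    "final_models": 10,
    "rebuild_termini": True,
    "terminal_rebuild_len": 3,
}


def default_config() -> dict[str, Any]:
    """A deep copy of the full default configuration."""
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | None = None, overrides: dict | None = None) -> dict[str, Any]:
    """Defaults, optionally updated from a YAML file and a dict of overrides.

    Nested dicts (weights, operator_weights, error_coeffs) are merged
    key-by-key; scalar keys are replaced.
    """
    cfg = default_config()
    layers = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        layers.append(loaded)
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, value in layer.items():
            if key not in cfg:
                raise KeyError(f"unknown config key: {key!r}")
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                for k2, v2 in value.items():
                    if k2 not in cfg[key]:
                        raise KeyError(f"unknown config key: {key}.{k2}")
                    cfg[key][k2] = v2
            else:
                cfg[key] = value
    return cfg


def scaled_relax_steps(cfg: dict[str, Any], scale: float) -> dict[str, int]:
    """Scale the three relaxation step counts, preserving their ratio.

    Returns the long/standard/short counts, each at least 1.
    """
    return {
        name: max(1, int(round(cfg[key] * scale)))
        for name, key in [
            ("long", "relax_steps_long"),
            ("standard", "relax_steps_standard"),
            ("short", "relax_steps_short"),
        ]
    }
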