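"""Synthetic inputs for the pipeline, generated at desk scale.

MD trajectories of CYP–ligand complexes are expensive to produce and no
deposited trajectory exists for the complexes this package analyses, so the
pipeline's inputs are emulated statistically:

* :func:`simulate_distance_series` — an Ornstein–Uhlenbeck (OU) process as a
  stand-in for the Fe–reactive-atom distance signal. The OU process is mean
  reverting and Gaussian in its stationary law, which matches the qualitative
  structure of bound-ligand distance traces (fluctuation about a stationary
  mean); an optional regime switch moves the stationary mean mid-series to
  emulate a detachment event.
* :func:`scenario_presets` — OU parameter sets whose stationary means equal
  the reported per-complex mean distances (see ``data/presets.tsv``).
* :func:`build_toy_complex` / :func:`embed_series_into_trajectory` — a toy
  protein–heme–ligand structure and a trajectory in which the ligand is
  rigidly placed each frame so that the Fe–reactive-atom distance equals a
  given series exactly.
* :func:`simulate_msa` — alignments with an exactly controlled number of
  substitutions at one reference-mapped column.

All generators are deterministic under their integer seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .conservation_msa import MSA
from .geometry_engine import DistanceSeries
from .structure_io import (
    AtomRecord,
    LigandSpec,
    Structure,
    Trajectory,
    find_heme_iron,
    select_reactive_atom,
)

logger = logging.getLogger(__name__)

#: Hard-sphere contact floor (nm) for generated Fe–reactive-atom distances.
CONTACT_FLOOR_NM = 0.15

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class OUParams:
    """Parameters of the exact-discretisation OU distance process.

    ``mu_nm`` is the stationary mean, ``theta_per_ps`` the mean-reversion
    rate (stationary SD = sigma/sqrt(2*theta)), ``sigma_nm_sqrtps`` the
    volatility and ``x0_nm`` the initial value (defaults to the mean).
    ``regime_switch`` is an optional ``(t_switch_ps, new_mu_nm)`` pair: from
    ``t_switch_ps`` onwards the process reverts to ``new_mu_nm`` instead,
    emulating ligand detachment.
    """

    mu_nm: float
    theta_per_ps: float
    sigma_nm_sqrtps: float
    x0_nm: float | None = None
    regime_switch: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.theta_per_ps <= 0:
            raise ValueError("theta_per_ps must be positive")
        if self.sigma_nm_sqrtps < 0:
            raise ValueError("sigma_nm_sqrtps must be non-negative")
        if self.mu_nm <= 0 or (self.x0_nm is not None and self.x0_nm <= 0):
            raise ValueError("mu_nm and x0_nm must be positive")

    @property
    def stationary_sd_nm(self) -> float:
        return self.sigma_nm_sqrtps / math.sqrt(2.0 * self.theta_per_ps)


@dataclass(frozen=True)
class ScenarioPreset:
    """A named ligand × allele scenario with its OU parameters."""

    name: str
    ligand: str
    allele: str
    ou: OUParams


def simulate_distance_series(
    p: OUParams, n_frames: int, dt_ps: float, seed: int, label: str = ""
) -> DistanceSeries:
    """Simulate an OU distance series with the exact discretisation

    ``x(t+dt) = mu + (x(t) - mu) * exp(-theta*dt) + noise_sd * z``

    with ``noise_sd = sigma * sqrt((1 - exp(-2*theta*dt)) / (2*theta))`` and
    ``z`` standard normal. After an optional regime switch, ``mu`` is
    replaced by the switch mean. Output values are floored at the 0.15 nm
    hard-sphere contact distance (the recursion itself is left exact);
    flooring events are logged.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dt_ps <= 0:
        raise ValueError("dt_ps must be positive")
    rng = np.random.default_rng(seed)
    a = math.exp(-p.theta_per_ps * dt_ps)
    noise_sd = p.sigma_nm_sqrtps * math.sqrt(
        (1.0 - a * a) / (2.0 * p.theta_per_ps)
    )
    times = dt_ps * np.arange(n_frames)
    mu = np.full(n_frames, p.mu_nm)
    if p.regime_switch is not None:
        t_switch, new_mu = p.regime_switch
        mu[times >= t_switch] = new_mu
    z = rng.standard_normal(n_frames - 1)
    x = np.empty(n_frames)
    x[0] = p.mu_nm if p.x0_nm is None else p.x0_nm
    for t in range(1, n_frames):
        x[t] = mu[t] + (x[t - 1] - mu[t]) * a + noise_sd * z[t - 1]
    n_floored = int(np.sum(x < CONTACT_FLOOR_NM))
    if n_floored:
        logger.info(
            "simulate_distance_series %r: floored %d/%d frames at %.2f nm",
            label, n_floored, n_frames, CONTACT_FLOOR_NM,
        )
    values = np.maximum(x, CONTACT_FLOOR_NM)
    return DistanceSeries(times_ps=times, values_nm=values, label=label)


def scenario_presets() -> list[ScenarioPreset]:
    """The shipped ligand × allele presets (see ``data/presets.tsv``).

    Ten presets carry numeric stationary means equal to the reported
    per-complex mean distances; the OTA:*122 preset instead carries a regime
    switch at 5 ns (an early detachment relative to a 50 ns run — no numeric
    mean is reported for that complex).
    """
    path = resources.files("hemedist") / "data" / "presets.tsv"
    with resources.as_file(path) as fp:
        df = pd.read_csv(fp, sep="\t", comment="#")
    presets = []
    for _, row in df.iterrows():
        switch = None
        if not pd.isna(row.get("t_switch_ps")):
            switch = (float(row["t_switch_ps"]), float(row["new_mu_nm"]))
        presets.append(
            ScenarioPreset(
                name=row["scenario"],
                ligand=row["ligand"],
                allele=row["allele"],
                ou=OUParams(
                    mu_nm=float(row["mu_nm"]),
                    theta_per_ps=float(row["theta_per_ps"]),
                    sigma_nm_sqrtps=float(row["sigma_nm_sqrtps"]),
                    x0_nm=float(row["x0_nm"]),
                    regime_switch=switch,
                ),
            )
        )
    return presets


def get_preset(name: str) -> ScenarioPreset:
    for preset in scenario_presets():
        if preset.name == name:
            return preset
    raise KeyError(f"no preset named {name!r}")


def build_toy_complex(
    n_residues: int = 30,
    lig: LigandSpec = LigandSpec("OTA", "C4", "OTA"),
    seed: int = 0,
) -> Structure:
    """A toy protein–heme–ligand complex for desk-scale testing.

    One protein chain (N, CA, C per residue) folded on a self-avoiding random
    walk of 3.8 Å C-alpha steps, one HEM residue holding a single FE atom
    near the walk's centroid, and one ligand residue containing the named
    reactive atom placed 4.5 Å from the iron. Deterministic under ``seed``.
    """
    if n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    rng = np.random.default_rng(seed)
    # Self-avoiding random walk for the C-alpha trace.
    ca = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        for _ in range(200):
            step = rng.standard_normal(3)
            step *= 3.8 / np.linalg.norm(step)
            cand = ca[i - 1] + step
            if np.all(np.linalg.norm(ca[: i - 1] - cand, axis=1) >= 3.5):
                ca[i] = cand
                break
        else:  # pragma: no cover - extremely unlikely at 3.5 Å exclusion
            raise RuntimeError("self-avoiding walk failed to extend")
    sequence = "".join(rng.choice(_AA, size=n_residues))
    three_letter = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n_residues):
        res = three_letter[sequence[i]]
        for name, element, off in (
            ("N", "N", (-1.2, 0.6, 0.0)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.2, 0.6, 0.0)),
        ):
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=element, res_name=res,
                    res_seq=i + 1, chain_id="A",
                    xyz=tuple(ca[i] + np.array(off)), hetero=False,
                )
            )
            serial += 1
    # Heme iron a short distance off the walk's centroid, outside the chain.
    centroid = ca.mean(axis=0)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    fe_xyz = centroid + 8.0 * direction
    atoms.append(
        AtomRecord(
            serial=serial, name="FE", element="FE", res_name="HEM",
            res_seq=n_residues + 1, chain_id="A", xyz=tuple(fe_xyz), hetero=True,
        )
    )
    serial += 1
    # Ligand: the reactive atom 4.5 Å from the iron plus two carrier carbons.
    lig_dir = rng.standard_normal(3)
    lig_dir /= np.linalg.norm(lig_dir)
    reactive_xyz = fe_xyz + 4.5 * lig_dir
    lig_atoms = [(lig.reactive_atom_name, reactive_xyz)]
    for k, off in enumerate(((1.5, 0.0, 0.0), (0.0, 1.5, 0.0)), start=1):
        name = f"C{k}" if f"C{k}" != lig.reactive_atom_name else f"C{k + 5}"
        lig_atoms.append((name, reactive_xyz + np.array(off)))
    for name, xyz in lig_atoms:
        atoms.append(
            AtomRecord(
                serial=serial, name=name,
                element=name[0] if not name[0].isdigit() else "C",
                res_name=lig.res_name, res_seq=n_residues + 2, chain_id="A",
                xyz=tuple(xyz), hetero=True,
            )
        )
        serial += 1
    return Structure(atoms=atoms, id=f"toy_complex_{lig.label or lig.res_name}")


def embed_series_into_trajectory(
    s: Structure,
    series: DistanceSeries,
    lig: LigandSpec,
    jitter_nm: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """A trajectory in which the Fe–reactive-atom distance follows ``series``.

    Per frame the whole ligand residue is rigidly translated so that the
    reactive atom sits exactly ``series.values_nm[f]`` from the iron along a
    fixed direction (measured before jitter). Independent Gaussian jitter of
    scale ``jitter_nm`` is applied to protein atoms only; the heme (and its
    iron) stays fixed, so the embedded distance signal is exact.
    """
    if np.min(series.values_nm) < CONTACT_FLOOR_NM:
        raise ValueError(
            f"series contains values below the {CONTACT_FLOOR_NM} nm contact floor"
        )
    fe_idx = find_heme_iron(s)
    ra_idx = select_reactive_atom(s, lig)
    base = s.coords()
    fe_xyz = base[fe_idx]
    u = base[ra_idx] - fe_xyz
    norm = np.linalg.norm(u)
    u = np.array([1.0, 0.0, 0.0]) if norm == 0 else u / norm
    lig_idx = np.array([i for i, a in enumerate(s.atoms) if a.res_name == lig.res_name])
    prot_idx = np.array([i for i, a in enumerate(s.atoms) if not a.hetero])
    n = series.n_frames
    frames = np.repeat(base[None, :, :], n, axis=0)
    # Translation placing the reactive atom at fe + d * u, per frame.
    targets = fe_xyz[None, :] + (series.values_nm[:, None] * 10.0) * u[None, :]
    shifts = targets - base[ra_idx][None, :]
    frames[:, lig_idx, :] += shifts[:, None, :]
    if jitter_nm > 0 and prot_idx.size:
        rng = np.random.default_rng(seed)
        frames[:, prot_idx, :] += rng.normal(
            scale=jitter_nm * 10.0, size=(n, prot_idx.size, 3)
        )
    dt = series.dt_ps() if n >= 2 else 10.0
    return Trajectory(
        structure=s, frames=frames, dt_ps=dt, t0_ps=float(series.times_ps[0])
    )


def simulate_msa(
    n_sequences: int,
    n_substituted: int,
    ref_seq: str,
    ref_position: int,
    substitution_alphabet: set[str],
    background_identity: float = 0.95,
    seed: int = 0,
) -> MSA:
    """A gapless alignment with an exactly controlled substitution count.

    Record 1 is the reference. Exactly ``n_substituted`` of the non-reference
    records carry a residue drawn from ``substitution_alphabet`` at the
    column mapped from ``ref_position``; the rest match the reference there.
    Every other column of a non-reference record mutates i.i.d. with
    probability ``1 - background_identity``.
    """
    L = len(ref_seq)
    if not (1 <= ref_position <= L):
        raise ValueError(f"ref_position {ref_position} outside sequence (length {L})")
    if not (0 <= n_substituted <= n_sequences - 1):
        raise ValueError(
            "n_substituted must lie between 0 and n_sequences - 1 "
            "(the reference is never substituted)"
        )
    if not (0.0 <= background_identity <= 1.0):
        raise ValueError("background_identity must be in [0, 1]")
    ref_seq = ref_seq.upper()
    ref_char = ref_seq[ref_position - 1]
    alphabet = sorted(set(substitution_alphabet) - {ref_char})
    if n_substituted > 0 and not alphabet:
        raise ValueError("substitution_alphabet holds no residue differing from the reference")
    rng = np.random.default_rng(seed)
    aa_index = {c: i for i, c in enumerate(_AA)}
    ref_codes = np.array([aa_index[c] for c in ref_seq], dtype=int)
    n_others = n_sequences - 1
    codes = np.tile(ref_codes, (n_others, 1))
    mutate = rng.random((n_others, L)) < (1.0 - background_identity)
    mutate[:, ref_position - 1] = False  # target column is controlled exactly
    # Shift by 1..19 modulo 20: guaranteed different from the original residue.
    codes[mutate] = (codes[mutate] + rng.integers(1, 20, size=int(mutate.sum()))) % 20
    chosen = rng.choice(n_others, size=n_substituted, replace=False)
    codes[chosen, ref_position - 1] = [
        aa_index[c] for c in rng.choice(alphabet, size=n_substituted)
    ]
    records = [("REF", ref_seq)]
    for i in range(n_others):
        records.append((f"seq{i + 2:05d}", "".join(_AA[codes[i]])))
    return MSA(records=records, ref_id="REF")
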