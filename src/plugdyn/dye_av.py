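"""Accessible-volume (AV) dye modelling and FRET-efficiency prediction.

A dye tethered by a flexible linker samples the sterically allowed volume
around its attachment atom.  The classic AV approximation treats the dye as
a sphere on a stiff linker of given length and width: candidate dye-centre
positions are Monte Carlo sampled inside the linker-length sphere, rejected
on steric clash with the structure, and accepted only when a clash-free
straight linker path connects them to the attachment point.  Inter-dye
distance distributions over two AV clouds convert to FRET efficiency via

    E = 1 / (1 + (r / R0)^6)

with R0 = 6 nm for the Alexa 488 / Alexa 594 pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.spatial import cKDTree

from .bursts import FormatError, ParameterError

__all__ = [
    "StructureModel",
    "AVCloud",
    "EfretPrediction",
    "BuriedSiteError",
    "load_structure",
    "compute_av",
    "distance_distribution",
    "efret_from_distances",
]

# van der Waals radii (Å) by element; fallback by atom-name initial
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "SE": 1.90, "FE": 1.40, "ZN": 1.39, "MG": 1.73}
DEFAULT_RADIUS = 1.70


class BuriedSiteError(RuntimeError):
    """No accessible dye positions: the attachment site is buried."""


@dataclass
class StructureModel:
    coords: np.ndarray                 # (N, 3) Å
    radii: np.ndarray                  # (N,) Å
    chain: np.ndarray
    resseq: np.ndarray
    atom_name: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise FormatError("radii must be positive")

    def find_atom(self, chain: str, resseq: int, atom_name: str) -> int:
        hit = np.flatnonzero((self.chain == chain) & (self.resseq == resseq)
                             & (self.atom_name == atom_name))
        if len(hit) == 0:
            raise KeyError(f"atom {chain}:{resseq}:{atom_name} not in structure")
        return int(hit[0])


def load_structure(path, strip_hetero: bool = True) -> StructureModel:
    """Load a PDB or mmCIF file into a flat atom table with vdW radii.

    Missing element assignments fall back to the atom-name initial (with a
    warning).  Waters and hetero groups are stripped by default.
    """
    import warnings

    from Bio.PDB import MMCIFParser, PDBParser

    path = str(path)
    parser = (MMCIFParser(QUIET=True) if path.lower().endswith((".cif", ".mmcif"))
              else PDBParser(QUIET=True))
    structure = parser.get_structure("s", path)
    coords, radii, chains, resseqs, names = [], [], [], [], []
    warned = False
    for model in structure:
        for chain in model:
            for res in chain:
                if strip_hetero and res.id[0] != " ":
                    continue
                for atom in res:
                    el = (atom.element or "").strip().upper()
                    if el not in VDW_RADII:
                        el2 = atom.get_name().strip()[:1].upper()
                        if el and not warned:
                            warnings.warn(
                                f"unknown element '{el}'; using atom-name fallback")
                            warned = True
                        el = el2
                    radii.append(VDW_RADII.get(el, DEFAULT_RADIUS))
                    coords.append(atom.coord)
                    chains.append(chain.id)
                    resseqs.append(res.id[1])
                    names.append(atom.get_name())
        break  # first model only
    if not coords:
        raise FormatError(f"no atoms read from {path}")
    return StructureModel(coords=np.asarray(coords, dtype=float),
                          radii=np.asarray(radii, dtype=float),
                          chain=np.asarray(chains),
                          resseq=np.asarray(resseqs, dtype=int),
                          atom_name=np.asarray(names))


@dataclass
class AVCloud:
    attachment: np.ndarray             # (3,) Å
    positions: np.ndarray              # (M, 3) Å accepted dye centres
    weights: np.ndarray
    linker_length: float
    linker_width: float
    dye_radius: float
    n_sampled: int

    @property
    def accepted_fraction(self) -> float:
        return len(self.positions) / self.n_sampled if self.n_sampled else 0.0

    def to_xyz(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.positions)}\nAV dye-centre cloud\n")
            for p in self.positions:
                fh.write(f"D {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")


def compute_av(structure: StructureModel, site: Tuple[str, int, str],
               linker_length: float = 20.0, linker_width: float = 4.5,
               dye_radius: float = 3.5, n_samples: int = 20000,
               seed: int = 0) -> AVCloud:
    """Monte Carlo accessible volume of a dye at an attachment site.

    Candidate centres are sampled uniformly in the linker-length sphere,
    discarded on clash with any atom (centre distance < atom vdW radius +
    dye radius), and kept only if a straight linker segment from the
    attachment to the candidate keeps a clearance of half the linker width.
    The attachment atom itself is excluded from clash checks.  Accepted
    positions carry uniform weights.
    """
    if linker_length <= 0 or linker_width <= 0 or dye_radius <= 0:
        raise ParameterError("linker/dye geometry must be positive")
    ai = structure.find_atom(*site)
    origin = structure.coords[ai]
    mask = np.ones(len(structure.coords), dtype=bool)
    mask[ai] = False
    atoms = structure.coords[mask]
    radii = structure.radii[mask]
    rng = np.random.default_rng(seed)
    # uniform sampling in a sphere
    u = rng.random(n_samples)
    r = linker_length * np.cbrt(u)
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cand = origin + r[:, None] * v

    if len(atoms) == 0:
        accepted = cand
    else:
        tree = cKDTree(atoms)
        rmax = float(radii.max())

        def clash_free(points: np.ndarray, clearance: float) -> np.ndarray:
            ok = np.ones(len(points), dtype=bool)
            neighbours = tree.query_ball_point(points, rmax + clearance)
            for i, nb in enumerate(neighbours):
                if nb:
                    d = np.linalg.norm(atoms[nb] - points[i], axis=1)
                    if np.any(d < radii[nb] + clearance):
                        ok[i] = False
            return ok

        ok = clash_free(cand, dye_radius)
        cand = cand[ok]
        # straight-segment linker reachability at half-width clearance
        if len(cand):
            n_seg = max(int(np.ceil(linker_length / linker_width)), 2)
            frac = np.linspace(0.15, 0.9, n_seg)
            keep = np.ones(len(cand), dtype=bool)
            for f in frac:
                pts = origin + f * (cand - origin)
                keep &= clash_free(pts, linker_width / 2.0)
            cand = cand[keep]
        accepted = cand
    if len(accepted) == 0:
        raise BuriedSiteError(f"site {site} is buried: no accessible positions")
    return AVCloud(attachment=origin, positions=accepted,
                   weights=np.full(len(accepted), 1.0 / len(accepted)),
                   linker_length=linker_length, linker_width=linker_width,
                   dye_radius=dye_radius, n_sampled=n_samples)


@dataclass
class DistanceDistribution:
    distances_nm: np.ndarray
    mean_nm: float
    sd_nm: float


def distance_distribution(av1: AVCloud, av2: AVCloud,
                          n_pairs: int = 100_000,
                          seed: int = 0) -> DistanceDistribution:
    """Inter-dye distance distribution over two AV clouds (nm).

    All position pairs are used when their number is small; otherwise
    ``n_pairs`` random pairs are drawn.
    """
    if len(av1.positions) == 0 or len(av2.positions) == 0:
        raise ParameterError("both AV clouds must be non-empty")
    n1, n2 = len(av1.positions), len(av2.positions)
    if n1 * n2 <= n_pairs:
        d = np.linalg.norm(av1.positions[:, None, :] - av2.positions[None, :, :],
                           axis=-1).ravel()
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n1, n_pairs)
        j = rng.integers(0, n2, n_pairs)
        d = np.linalg.norm(av1.positions[i] - av2.positions[j], axis=1)
    d_nm = d / 10.0
    return DistanceDistribution(distances_nm=d_nm, mean_nm=float(d_nm.mean()),
                                sd_nm=float(d_nm.std()))


@dataclass
class EfretPrediction:
    r0_nm: float
    efficiencies: np.ndarray
    hist: np.ndarray
    edges: np.ndarray

    @property
    def mean_e(self) -> float:
        return float(self.efficiencies.mean())


def efret_from_distances(distances_nm, r0_nm: float = 6.0,
                         n_bins: int = 50) -> EfretPrediction:
    """Förster conversion of inter-dye distances to FRET efficiencies,
    E = 1 / (1 + (r/R0)^6), histogrammed on [0, 1]."""
    if r0_nm <= 0:
        raise ParameterError("Förster radius must be positive")
    r = np.asarray(distances_nm, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("distances must be positive")
    e = 1.0 / (1.0 + (r / r0_nm) ** 6)
    hist, edges = np.histogram(e, bins=n_bins, range=(0.0, 1.0), density=True)
    return EfretPrediction(r0_nm=r0_nm, efficiencies=e, hist=hist, edges=edges)
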