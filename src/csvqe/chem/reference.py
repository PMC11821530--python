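"""Reference wavefunction data and the classical benchmark suite.

Bundles per-geometry quantities the subspace methods consume (MO energies,
MP2/CCSD amplitudes, natural occupations) and exposes the conventional
quantum-chemistry benchmarks: HF (restricted, = ROHF for the closed-shell
singlets treated here), MP2, CISD, CCSD, CCSD(T), CASCI and FCI.  CASCI
active spaces are selected from MP2 natural orbitals: orbitals are ranked
by natural occupation, the most occupied become the doubly occupied core
(fixing the electron count) and the next M_act form the active window
around the Fermi level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cc import ccsd, ccsd_t, mp2, mp2_natural_occupations
from .ci import casci_ground, cisd_ground, fci_ground, DeterminantSpace
from .molecule import MolecularGeometry
from .scf import SCFResult, run_rhf

__all__ = ["ReferenceData", "build_reference_data", "run_benchmarks",
           "SUPPORTED_METHODS"]

SUPPORTED_METHODS = ("HF", "ROHF", "MP2", "CISD", "CCSD", "CCSD(T)",
                     "CASCI", "FCI")


@dataclass
class ReferenceData:
    mo_energies: np.ndarray
    hf_energy: float
    mp2_t2: np.ndarray
    ccsd_t1: np.ndarray | None
    ccsd_t2: np.ndarray | None
    natural_occupations: np.ndarray
    energies: dict = field(default_factory=dict)

    @property
    def n_orbitals(self) -> int:
        return len(self.mo_energies)

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return json.dumps({
            "mo_energies": arr(self.mo_energies),
            "hf_energy": self.hf_energy,
            "mp2_t2": arr(self.mp2_t2),
            "ccsd_t1": arr(self.ccsd_t1),
            "ccsd_t2": arr(self.ccsd_t2),
            "natural_occupations": arr(self.natural_occupations),
            "energies": self.energies,
        })

    @classmethod
    def from_json(cls, s: str) -> "ReferenceData":
        d = json.loads(s)

        def arr(a):
            return None if a is None else np.array(a)

        return cls(arr(d["mo_energies"]), d["hf_energy"], arr(d["mp2_t2"]),
                   arr(d["ccsd_t1"]), arr(d["ccsd_t2"]),
                   arr(d["natural_occupations"]), d["energies"])


def build_reference_data(source: MolecularGeometry | SCFResult,
                         with_ccsd: bool = True) -> ReferenceData:
    scf = source if isinstance(source, SCFResult) else run_rhf(source)
    m = mp2(scf)
    occ, _ = mp2_natural_occupations(scf)
    t1 = t2 = None
    energies = {"HF": scf.e_hf, "MP2": scf.e_hf + m.e_corr}
    if with_ccsd:
        cc = ccsd(scf)
        t1, t2 = cc.t1, cc.t2
        energies["CCSD"] = scf.e_hf + cc.e_corr
    return ReferenceData(scf.mo_energies.copy(), scf.e_hf, m.t2, t1, t2,
                         occ, energies)


def _cas_orbitals(scf: SCFResult, m_act: int, n_act: int):
    """Natural orbitals partitioned into (core, active) for CASCI."""
    if n_act % 2 != 0:
        raise ValueError("active electron count must be even (closed shell)")
    occ, U = mp2_natural_occupations(scf)   # descending occupation
    n_core = (scf.geometry.n_electrons - n_act) // 2
    if n_core < 0 or n_core + m_act > scf.n_orb:
        raise ValueError(f"active space ({m_act}o,{n_act}e) does not fit")
    core = list(range(n_core))
    active = list(range(n_core, n_core + m_act))
    return U, core, active


def run_benchmarks(geom: MolecularGeometry, methods,
                   active_space: tuple[int, int] | None = None,
                   scf: SCFResult | None = None,
                   space: DeterminantSpace | None = None) -> dict:
    """Energies (Hartree) for the requested methods.

    ``active_space`` = (M_act orbitals, N_act electrons), required for
    CASCI.  CASSCF (orbital-optimised CAS) is not provided by this engine.
    """
    methods = [m.upper().replace(" ", "") for m in methods]
    for m in methods:
        if m == "CASSCF":
            raise ValueError("CASSCF is not supported by the built-in "
                             "engine; use CASCI")
        if m not in SUPPORTED_METHODS:
            raise ValueError(f"unsupported method {m!r}; supported: "
                             f"{SUPPORTED_METHODS}")
    scf = scf or run_rhf(geom)
    out: dict[str, float] = {}
    h = g = None
    cc_res = None
    for m in methods:
        if m in ("HF", "ROHF"):
            out[m] = scf.e_hf
            continue
        if m == "MP2":
            out[m] = scf.e_hf + mp2(scf).e_corr
            continue
        if m == "CCSD":
            cc_res = cc_res or ccsd(scf)
            out[m] = scf.e_hf + cc_res.e_corr
            continue
        if m == "CCSD(T)":
            cc_res = cc_res or ccsd(scf)
            e_t, _ = ccsd_t(scf, cc_res)
            out[m] = scf.e_hf + cc_res.e_corr + e_t
            continue
        if h is None:
            h, g = scf.mo_hcore(), scf.mo_eri()
        if m == "CISD":
            na = scf.n_occ
            out[m] = cisd_ground(h, g, scf.n_orb, na, na, scf.e_nuc,
                                 space=space)
        elif m == "FCI":
            na = scf.n_occ
            out[m] = fci_ground(h, g, scf.n_orb, na, na, scf.e_nuc,
                                space=space)
        elif m == "CASCI":
            if active_space is None:
                raise ValueError("CASCI requires active_space=(M, N)")
            m_act, n_act = active_space
            U, core, active = _cas_orbitals(scf, m_act, n_act)
            hno = U.T @ h @ U
            gno = np.einsum("ijkl,ip,jq,kr,ls->pqrs", g, U, U, U, U,
                            optimize=True)
            out[m] = casci_ground(hno, gno, core, active, n_act, scf.e_nuc)
    return out
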