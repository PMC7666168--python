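"""File I/O: PDB/mmCIF structures via gemmi, tables via pandas, results JSON.

Column schemas
--------------
decay tables (CSV/TSV): residue, x, height, sigma [, spinlock_nu, offset_omega]
dispersion profiles:    residue, omega1, r1rho, r1rho_err
restraint lists:        atom_a, atom_b, upper_bound, intermolecular_only
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .relaxation import DispersionProfile, RelaxationDecay
from .synthetic import SyntheticMonomer

__all__ = [
    "write_structure", "read_monomer",
    "decays_to_frame", "frame_to_decays",
    "profiles_to_frame", "frame_to_profiles",
    "read_restraint_table", "write_restraint_table",
    "dispersion_results_to_dict", "write_json",
]


def _label_parts(label):
    res, atom = label.split(":")
    return int(res[1:]), atom


def write_structure(path, monomer, assembly=None):
    """Write a monomer (single chain) or an assembly (chain per subunit).

    Pseudo-atoms are emitted as glycine CA-style records; the format (PDB or
    mmCIF) follows the file extension.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "tubeflex model"
    model = gemmi.Model("1")

    def add_chain(cid, labels, positions):
        chain = gemmi.Chain(cid)
        for lab, pos in zip(labels, positions):
            resnum, atomname = _label_parts(lab)
            residue = gemmi.Residue()
            residue.name = "GLY"
            residue.seqid = gemmi.SeqId(resnum + 1, " ")
            atom = gemmi.Atom()
            atom.name = atomname
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*pos)
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)

    if assembly is None:
        add_chain("A", monomer.labels, monomer.positions)
    else:
        for i in range(assembly.n_subunits):
            add_chain(assembly.chain_ids[i], assembly.monomer.labels,
                      assembly.positions(i))
    st.add_model(model)
    st.setup_entities()
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


def read_monomer(path, chain: str = "A") -> SyntheticMonomer:
    """Read one chain of a PDB/mmCIF file back as a pseudo-atom monomer."""
    import gemmi

    st = gemmi.read_structure(str(path))
    model = st[0]
    labels, positions = [], []
    for ch in model:
        if ch.name != chain:
            continue
        for residue in ch:
            for atom in residue:
                labels.append(f"R{residue.seqid.num - 1}:{atom.name}")
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not labels:
        raise ValueError(f"chain {chain!r} not found in {path}")
    return SyntheticMonomer(labels, np.array(positions))


def decays_to_frame(decays) -> pd.DataFrame:
    rows = []
    for d in decays:
        for x, h in zip(d.x, d.heights):
            rows.append({"residue": d.residue, "x": x, "height": h,
                         "sigma": d.sigma, "spinlock_nu": d.spinlock_nu,
                         "offset_omega": d.offset_omega})
    return pd.DataFrame(rows)


def frame_to_decays(df: pd.DataFrame):
    decays = []
    keys = ["residue"] + [c for c in ("spinlock_nu",) if c in df.columns]
    for _, grp in df.groupby(keys, dropna=False, sort=False):
        grp = grp.sort_values("x")
        first = grp.iloc[0]
        sl = first.get("spinlock_nu")
        off = first.get("offset_omega")
        decays.append(RelaxationDecay(
            str(first["residue"]), grp["x"].to_numpy(),
            grp["height"].to_numpy(),
            sigma=None if pd.isna(first.get("sigma")) else float(first["sigma"]),
            spinlock_nu=None if pd.isna(sl) else float(sl),
            offset_omega=None if off is None or pd.isna(off) else float(off)))
    return decays


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for w, r, e in zip(p.omega1, p.r1rho, p.r1rho_err):
            rows.append({"residue": p.residue, "omega1": w, "r1rho": r,
                         "r1rho_err": e})
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame):
    out = []
    for residue, grp in df.groupby("residue", sort=False):
        grp = grp.sort_values("omega1")
        out.append(DispersionProfile(str(residue), grp["omega1"].to_numpy(),
                                     grp["r1rho"].to_numpy(),
                                     grp["r1rho_err"].to_numpy()))
    return out


def read_restraint_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"atom_a", "atom_b"}
    if not required <= set(df.columns):
        raise ValueError(f"restraint table needs columns {sorted(required)}")
    if "upper_bound" not in df.columns:
        df["upper_bound"] = 7.0
    if "intermolecular_only" not in df.columns:
        df["intermolecular_only"] = False
    return df


def write_restraint_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def dispersion_results_to_dict(results) -> dict:
    d = {"k_ex": results.k_ex, "k_ex_err": results.k_ex_err,
         "k_ex_identifiable": results.k_ex_identifiable,
         "chi2": results.chi2, "n_mc": results.n_mc, "residues": {}}
    for i, res in enumerate(results.residues):
        d["residues"][res] = {
            "phi_ex": float(results.phi_ex[i]),
            "phi_ex_err": (None if results.phi_ex_err is None
                           else float(results.phi_ex_err[i])),
            "r1rho0": float(results.r1rho0[i]),
            "r1rho0_err": (None if results.r1rho0_err is None
                           else float(results.r1rho0_err[i]))}
    return d


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
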