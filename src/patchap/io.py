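"""File formats: meshes (OBJ / TSV pair), matrices (TSV + JSON sidecar),
results (JSON), configs (YAML).  All numeric text output keeps full double
precision; all indices on disk are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .mesh import TriangleMesh

__all__ = [
    "save_mesh_obj", "load_mesh_obj", "save_mesh_tsv", "load_mesh_tsv",
    "save_matrix_tsv", "load_matrix_tsv", "save_json", "load_json",
    "load_yaml",
]

_FMT = "%.17g"


def save_mesh_obj(mesh: TriangleMesh, path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_text(
        trimesh.exchange.obj.export_obj(tm, include_normals=False,
                                        include_texture=False)
    )


def load_mesh_obj(path) -> TriangleMesh:
    tm = trimesh.load(str(path), file_type="obj", process=False,
                      maintain_order=True)
    return TriangleMesh(vertices=np.asarray(tm.vertices),
                        faces=np.asarray(tm.faces))


def save_mesh_tsv(mesh: TriangleMesh, vertices_path, faces_path) -> None:
    np.savetxt(vertices_path, mesh.vertices, fmt=_FMT, delimiter="\t")
    np.savetxt(faces_path, mesh.faces, fmt="%d", delimiter="\t")


def load_mesh_tsv(vertices_path, faces_path) -> TriangleMesh:
    vertices = np.loadtxt(vertices_path, delimiter="\t", ndmin=2)
    faces = np.loadtxt(faces_path, delimiter="\t", dtype=int, ndmin=2)
    return TriangleMesh(vertices=vertices, faces=faces)


def save_matrix_tsv(matrix: np.ndarray, path, sidecar: dict | None = None) -> None:
    np.savetxt(path, np.atleast_2d(matrix), fmt=_FMT, delimiter="\t")
    if sidecar is not None:
        save_json(sidecar, str(path) + ".json")


def load_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
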