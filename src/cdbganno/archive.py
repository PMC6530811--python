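"""The on-disk archive container.

An archive is a magic string, a version, and an ordered list of tagged,
length-prefixed sections.  Sections used by the tool:

  GRAPH    — k, sentinel flag, and sorted k-mer/edge-id pairs
  MATMETA  — JSON: color names, indicator count, matrix shape
  MATRIX   — packed annotation-matrix bits (written by ``build``)
  WTRIE    — serialized wavelet trie
  BLOOM    — per-filter headers and packed filter bits

Corrected Bloom queries need the GRAPH section at decode time; the wavelet
trie does not.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Tuple

import numpy as np

from .annotation import AnnotationMatrix
from .graph import KmerGraph

MAGIC = b"CDBGANN\x01"
VERSION = 1

TAG_GRAPH = "GRAPH"
TAG_MATMETA = "MATMETA"
TAG_MATRIX = "MATRIX"
TAG_WTRIE = "WTRIE"
TAG_BLOOM = "BLOOM"
_KNOWN_TAGS = {TAG_GRAPH, TAG_MATMETA, TAG_MATRIX, TAG_WTRIE, TAG_BLOOM}


class ArchiveFormatError(ValueError):
    pass


def write_archive(path: str, sections: List[Tuple[str, bytes]]) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(VERSION.to_bytes(2, "big"))
        for tag, payload in sections:
            if tag not in _KNOWN_TAGS:
                raise ArchiveFormatError(f"unknown section tag {tag!r}")
            fh.write(tag.encode("ascii").ljust(8))
            fh.write(len(payload).to_bytes(8, "big"))
            fh.write(payload)


def read_archive(path: str) -> Dict[str, bytes]:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[: len(MAGIC)] != MAGIC:
        raise ArchiveFormatError(f"{path}: not an annotation archive (bad magic)")
    version = int.from_bytes(data[len(MAGIC) : len(MAGIC) + 2], "big")
    if version != VERSION:
        raise ArchiveFormatError(f"{path}: unsupported archive version {version}")
    off = len(MAGIC) + 2
    sections: Dict[str, bytes] = {}
    while off < len(data):
        if off + 16 > len(data):
            raise ArchiveFormatError(f"{path}: truncated section header")
        tag = data[off : off + 8].decode("ascii").rstrip()
        length = int.from_bytes(data[off + 8 : off + 16], "big")
        off += 16
        if off + length > len(data):
            raise ArchiveFormatError(f"{path}: section {tag} overruns file")
        sections[tag] = data[off : off + length]
        off += length
    return sections


# -- section codecs ---------------------------------------------------------

def encode_graph(g: KmerGraph) -> bytes:
    head = f"k={g.k}\tsentinels={int(g.sentinels)}\tn={g.n_edges}\n"
    pairs = sorted((km, i) for i, km in enumerate(g.kmers, start=1))
    body = "".join(f"{km}\t{i}\n" for km, i in pairs)
    return (head + body).encode("ascii")


def decode_graph(payload: bytes) -> KmerGraph:
    lines = payload.decode("ascii").splitlines()
    if not lines:
        raise ArchiveFormatError("empty GRAPH section")
    fields = dict(kv.split("=") for kv in lines[0].split("\t"))
    g = KmerGraph(int(fields["k"]), sentinels=bool(int(fields["sentinels"])))
    n = int(fields["n"])
    by_id = [None] * n
    for ln in lines[1:]:
        km, eid = ln.rsplit("\t", 1)
        by_id[int(eid) - 1] = km
    if any(km is None for km in by_id):
        raise ArchiveFormatError("GRAPH section: edge ids not a bijection onto 1..n")
    for km in by_id:
        g.add_kmer(km)
    return g


def encode_matrix_meta(a: AnnotationMatrix) -> bytes:
    return encode_meta_fields(a.color_names, a.indicator_count, a.n, a.m)


def encode_meta_fields(
    color_names: List[str], indicator_count: int, n: int, m: int
) -> bytes:
    return json.dumps(
        {
            "color_names": list(color_names),
            "indicator_count": indicator_count,
            "n": n,
            "m": m,
        }
    ).encode()


def encode_matrix_bits(a: AnnotationMatrix) -> bytes:
    return np.packbits(a.matrix.reshape(-1)).tobytes()


def decode_matrix(meta_payload: bytes, bits_payload: Optional[bytes]) -> AnnotationMatrix:
    meta = json.loads(meta_payload.decode())
    n, m = meta["n"], meta["m"]
    if bits_payload is None:
        mat = np.zeros((n, m), dtype=np.uint8)
    else:
        mat = np.unpackbits(
            np.frombuffer(bits_payload, dtype=np.uint8), count=n * m
        ).reshape(n, m)
    return AnnotationMatrix(mat, meta["color_names"], meta["indicator_count"])
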