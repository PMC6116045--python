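"""Glue: extract all four feature blocks per record and assemble matrices."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import SchemaError
from .features_composition import features_188d
from .features_evolutionary import (
    DwtConfig,
    SegmentSpec,
    local_dpp,
    normalize_pssm,
    pssm_dwt,
)
from .features_structure import AcConfig, ac_struct
from .io_formats import FeatureBlock, ProteinRecord, PssmProfile, SsProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureParams:
    """Every tunable feature-extraction parameter with its default."""

    local_dpp_n: int = 2
    local_dpp_lambda: int = 2
    dwt_levels: int = 4
    dwt_wavelet: str = "haar"
    dwt_leading_detail_count: int = 5
    ac_l_min: int = 50
    d188_distribution: str = "percentile"

    def segment_spec(self) -> SegmentSpec:
        return SegmentSpec(n=self.local_dpp_n, lam=self.local_dpp_lambda)

    def dwt_config(self) -> DwtConfig:
        return DwtConfig(
            levels=self.dwt_levels,
            wavelet_name=self.dwt_wavelet,
            leading_detail_count=self.dwt_leading_detail_count,
        )

    def ac_config(self) -> AcConfig:
        return AcConfig(l_min=self.ac_l_min)

    def as_dict(self) -> dict:
        return asdict(self)


def extract_record(
    record: ProteinRecord,
    pssm: PssmProfile,
    ss: SsProfile,
    params: FeatureParams = FeatureParams(),
) -> list[FeatureBlock]:
    """The four feature blocks of one protein, in canonical block order."""
    if len(pssm) != len(record):
        raise SchemaError(
            f"record {record.id!r}: PSSM has {len(pssm)} rows for a "
            f"{len(record)}-residue sequence"
        )
    if len(ss) != len(record):
        raise SchemaError(
            f"record {record.id!r}: SS profile has {len(ss)} rows for a "
            f"{len(record)}-residue sequence"
        )
    npssm = normalize_pssm(pssm)
    return [
        local_dpp(npssm, params.segment_spec()),
        pssm_dwt(npssm, params.dwt_config()),
        features_188d(record.sequence, params.d188_distribution),
        ac_struct(ss, params.ac_config()),
    ]


def extract_dataset(
    records: Sequence[ProteinRecord],
    pssms: Mapping[str, PssmProfile],
    ss: Mapping[str, SsProfile],
    params: FeatureParams = FeatureParams(),
):
    """Extract blocks for every record; per-record failures are logged and
    skipped. Returns ``(blocks_per_record, labels, skipped_ids)``."""
    blocks_per_record: dict[str, list[FeatureBlock]] = {}
    labels: dict[str, int] = {}
    skipped: list[str] = []
    for record in records:
        try:
            blocks_per_record[record.id] = extract_record(
                record, pssms[record.id], ss[record.id], params
            )
        except (KeyError, ValueError, SchemaError) as exc:
            logger.warning("skipping %s: %s", record.id, exc)
            skipped.append(record.id)
            continue
        if record.label is not None:
            labels[record.id] = record.label
    return blocks_per_record, labels, skipped


def blocks_to_matrices(
    blocks_per_record: Mapping[str, Sequence[FeatureBlock]],
    ids: Optional[Sequence[str]] = None,
):
    """Stack per-record blocks into one matrix per block name.

    Returns ``(matrices, ids)`` with rows in ``ids`` order.
    """
    if ids is None:
        ids = list(blocks_per_record)
    if not ids:
        raise SchemaError("no records to assemble")
    names = [b.block_name for b in blocks_per_record[ids[0]]]
    matrices = {
        name: np.vstack(
            [blocks_per_record[rid][i].values for rid in ids]
        )
        for i, name in enumerate(names)
    }
    return matrices, list(ids)
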