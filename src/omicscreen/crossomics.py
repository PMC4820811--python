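"""Cross-omics candidate intersection.

The final prioritization step: a candidate must be flagged in the
transcriptome consensus AND in the proteome screen(s), with the same
direction of change everywhere.  Identifier spaces are aligned explicitly
through a mapping table; unmapped ids are reported, never silently dropped.
"""

from __future__ import annotations

import pandas as pd

ANY_PLATFORM = "any_platform"
ALL_PLATFORMS = "all_platforms"


class MappingError(ValueError):
    """Raised for ambiguous transcript/protein identifier mappings."""


def map_ids(
    transcript_ids,
    protein_ids,
    mapping: pd.DataFrame | None = None,
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Align transcript and protein identifier spaces.

    ``mapping`` is a two-column DataFrame (``transcript_id``,
    ``protein_id``); None means identity mapping.  Returns
    (transcript_id -> protein_id over the aligned universe, report of
    unmapped ids per side).  Duplicate mappings on either side are an
    error.
    """
    t_ids, p_ids = set(transcript_ids), set(protein_ids)
    if mapping is None:
        aligned = {t: t for t in t_ids & p_ids}
        unmapped = {
            "transcripts": sorted(t_ids - p_ids),
            "proteins": sorted(p_ids - t_ids),
        }
        return aligned, unmapped
    if mapping["transcript_id"].duplicated().any() or mapping["protein_id"].duplicated().any():
        raise MappingError("mapping table is not one-to-one")
    pairs = dict(zip(mapping["transcript_id"], mapping["protein_id"]))
    aligned = {t: p for t, p in pairs.items() if t in t_ids and p in p_ids}
    unmapped = {
        "transcripts": sorted(t_ids - set(aligned)),
        "proteins": sorted(p_ids - set(aligned.values())),
    }
    return aligned, unmapped


def intersect_candidates(
    transcript_hits: dict[str, str],
    proteome_hits: dict[str, dict[str, str]],
    id_map: dict[str, str] | None = None,
    mode: str = ALL_PLATFORMS,
    transcript_log2fc: pd.Series | None = None,
    protein_log2fc: dict[str, pd.Series] | None = None,
    require_direction_consistency: bool = True,
) -> pd.DataFrame:
    """Direction-consistent intersection of the two screens.

    Parameters
    ----------
    transcript_hits
        feature_id -> direction from the transcriptome consensus.
    proteome_hits
        platform label -> {protein_id -> direction}.
    id_map
        transcript_id -> protein_id alignment from :func:`map_ids`
        (identity if None).
    mode
        ``all_platforms`` (default) requires the protein hit on every
        platform; ``any_platform`` on at least one.
    require_direction_consistency
        When True (default) a candidate whose recorded directions conflict
        anywhere is excluded.

    Returns a CandidateReport DataFrame (one row per candidate) with the
    direction, per-screen effect sizes when supplied, and per-platform
    support flags.  An empty result is valid.
    """
    if mode not in (ANY_PLATFORM, ALL_PLATFORMS):
        raise ValueError(f"unknown mode {mode!r}")
    if not proteome_hits:
        raise ValueError("at least one proteome hit set is required")
    id_map = id_map if id_map is not None else {t: t for t in transcript_hits}
    rows = []
    for t_id, t_dir in transcript_hits.items():
        p_id = id_map.get(t_id)
        if p_id is None:
            continue
        support = {plat: hits.get(p_id) for plat, hits in proteome_hits.items()}
        present = [d for d in support.values() if d is not None]
        if mode == ALL_PLATFORMS and len(present) < len(proteome_hits):
            continue
        if not present:
            continue
        directions = set(present) | {t_dir}
        if require_direction_consistency and len(directions) > 1:
            continue
        row = {
            "candidate_id": t_id,
            "protein_id": p_id,
            "direction": t_dir,
            "n_platforms_support": len(present),
        }
        if transcript_log2fc is not None:
            row["transcript_log2fc"] = float(transcript_log2fc.get(t_id, float("nan")))
        for plat in proteome_hits:
            row[f"{plat}_direction"] = support[plat] or "none"
            if protein_log2fc and plat in protein_log2fc:
                row[f"{plat}_log2fc"] = float(
                    protein_log2fc[plat].get(p_id, float("nan"))
                )
        rows.append(row)
    cols = ["candidate_id", "protein_id", "direction", "n_platforms_support"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
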