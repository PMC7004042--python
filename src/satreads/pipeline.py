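"""End-to-end workflow: reads + hit tables -> arrays, coded reads,
length distributions, flank/domain profiles and periodicity spectra.

Each stage is a thin orchestration of the library modules; a run writes a
deterministic directory of TSV/JSON outputs plus a manifest recording the
configuration and input checksums, so identical inputs and configuration
give identical results.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import pandas as pd

from . import annotation, io, periodicity, profiles, stats
from .config import RunConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    config: RunConfig,
    reads_path: str | Path,
    hits_path: str | Path,
    refdb_fasta: str | Path,
    refdb_annotation: str | Path,
    out_dir: str | Path,
    domains_path: str | Path | None = None,
) -> Path:
    """Run every stage and write the result directory.  Returns ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "reads": Path(reads_path),
        "hits": Path(hits_path),
        "refdb_fasta": Path(refdb_fasta),
        "refdb_annotation": Path(refdb_annotation),
    }
    if domains_path is not None:
        inputs["domains"] = Path(domains_path)
    for name, path in inputs.items():
        if not path.exists():
            raise StageError(f"inputs: missing {name} file: {path}")

    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = round(time.perf_counter() - timings[name], 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    # --- ingest -----------------------------------------------------------
    name = stage("ingest")
    try:
        reference = io.read_reference_database(
            inputs["refdb_fasta"], inputs["refdb_annotation"]
        )
        classes = io.family_classes(reference)
        code_map = annotation.make_code_map(reference)
        reads = list(io.read_sequences(inputs["reads"], config.min_read_length))
        read_lengths = {r.read_id: r.length for r in reads}
        hits = list(io.parse_hit_table(inputs["hits"], config.hit_dialect))
    except Exception as exc:
        raise StageError(f"ingest: {exc}") from exc
    done(name)

    # --- annotate ---------------------------------------------------------
    name = stage("annotate")
    try:
        hits = [h for h in hits if h.read_id in read_lengths]
        filtered = list(
            annotation.filter_hits(hits, config.min_score, config.max_length_ratio)
        )
        array_tier = [
            h for h in filtered
            if classes.get(h.family_id, "satellite") != "dispersed"
        ]
        dispersed_tier = [
            h for h in filtered
            if classes.get(h.family_id, "satellite") == "dispersed"
        ]
        arrays = annotation.merge_hits_to_arrays(
            array_tier, classes, config.min_array_length, config.max_gap
        )
        arrays = [
            annotation.classify_truncation(
                a, read_lengths[a.read_id], config.edge_tolerance
            )
            for a in arrays
        ]
        disp_by_read: dict[str, list] = {}
        for h in dispersed_tier:
            disp_by_read.setdefault(h.read_id, []).append(h)
        arrays_by_read: dict[str, list] = {}
        for a in arrays:
            arrays_by_read.setdefault(a.read_id, []).append(a)
        coded = {
            r.read_id: annotation.encode_read(
                r.length,
                arrays_by_read.get(r.read_id, []),
                disp_by_read.get(r.read_id, []),
                code_map,
            )
            for r in reads
        }
    except Exception as exc:
        raise StageError(f"annotate: {exc}") from exc
    annotation.arrays_to_frame(arrays).to_csv(
        out_dir / "arrays.tsv", sep="\t", index=False
    )
    annotation.coded_reads_to_frame(coded.values()).to_csv(
        out_dir / "coded_reads.tsv", sep="\t", index=False
    )
    io.write_json(code_map, out_dir / "code_map.json")
    done(name)

    # --- lengths ----------------------------------------------------------
    name = stage("lengths")
    try:
        histograms = stats.length_histograms(
            arrays, config.histogram_bin, config.histogram_last_bin
        )
        stats.histograms_to_frame(histograms).to_csv(
            out_dir / "length_histograms.tsv", sep="\t", index=False
        )
        stats.read_length_distribution(
            arrays, read_lengths, config.histogram_bin
        ).to_csv(out_dir / "read_length_distributions.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(f"lengths: {exc}") from exc
    done(name)

    # --- flanks -----------------------------------------------------------
    name = stage("flanks")
    try:
        flank_frames = []
        for family in sorted({a.family_id for a in arrays}):
            fam_arrays = [a for a in arrays if a.family_id == family]
            profile = profiles.flank_composition(
                coded, fam_arrays, config.flank_window, config.report_threshold
            )
            flank_frames.append(profile.to_frame())
        (
            pd.concat([f for f in flank_frames if len(f)], ignore_index=True)
            if any(len(f) for f in flank_frames)
            else pd.DataFrame(
                columns=["focal_family", "position", "repeat_code",
                         "proportion", "n_available"]
            )
        ).to_csv(out_dir / "flank_profiles.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(f"flanks: {exc}") from exc
    done(name)

    # --- domains ----------------------------------------------------------
    if domains_path is not None:
        name = stage("domains")
        try:
            cutoffs = profiles.DomainCutoffs(
                config.domain_min_identity,
                config.domain_min_similarity,
                config.domain_min_aln_length,
                config.domain_max_interruptions,
                config.domain_max_length_proportion,
            )
            domain_hits = profiles.filter_domain_hits(
                io.parse_domain_table(inputs["domains"]), cutoffs
            )
            domain_frames = []
            for family in sorted({a.family_id for a in arrays}):
                fam_arrays = [a for a in arrays if a.family_id == family]
                profile = profiles.domain_profile(
                    domain_hits, fam_arrays, read_lengths, config.flank_window
                )
                domain_frames.append(profile.to_frame())
            (
                pd.concat([f for f in domain_frames if len(f)], ignore_index=True)
                if any(len(f) for f in domain_frames)
                else pd.DataFrame(
                    columns=["focal_family", "position", "domain",
                             "relative_orientation", "proportion", "n_available"]
                )
            ).to_csv(out_dir / "domain_profiles.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"domains: {exc}") from exc
        done(name)

    # --- periodicity ------------------------------------------------------
    name = stage("periodicity")
    try:
        sequences = {r.read_id: r.sequence for r in reads}
        spectra_frames, peak_frames, acf_frames = [], [], []
        for family in sorted({a.family_id for a in arrays}):
            fam_arrays = [a for a in arrays if a.family_id == family]
            selected = periodicity.select_long_arrays(
                fam_arrays, sequences, config.periodicity_min_array
            )
            if not selected:
                logger.warning(
                    "periodicity: no arrays of %s reach %d bp; skipped",
                    family, config.periodicity_min_array,
                )
                continue
            spectra = [
                periodicity.fft_spectrum(seq, family_id=family)
                for _, seq in selected
            ]
            averaged = periodicity.average_spectra(spectra, family_id=family)
            spectra_frames.append(averaged.to_frame())
            peaks = periodicity.call_peaks(averaged)
            peak_frames.append(periodicity.peaks_to_frame(peaks, family))
            acfs = [
                periodicity.autocorrelation(
                    seq, config.autocorr_max_lag, config.autocorr_min_lag, family
                ).to_frame()
                for _, seq in selected
                if len(seq) > config.autocorr_max_lag
            ]
            if acfs:
                mean_acf = (
                    pd.concat(acfs)
                    .groupby(["family_id", "lag"], as_index=False)
                    .mean()
                )
                acf_frames.append(mean_acf)
        for frames, filename, columns in (
            (spectra_frames, "spectra.tsv",
             ["family_id", "period_bp", "amplitude", "n_arrays"]),
            (peak_frames, "peaks.tsv",
             ["family_id", "period_bp", "amplitude", "is_harmonic",
              "parent_period"]),
            (acf_frames, "autocorrelation.tsv", ["family_id", "lag"]),
        ):
            (
                pd.concat([f for f in frames if len(f)], ignore_index=True)
                if any(len(f) for f in frames)
                else pd.DataFrame(columns=columns)
            ).to_csv(out_dir / filename, sep="\t", index=False)
    except Exception as exc:
        raise StageError(f"periodicity: {exc}") from exc
    done(name)

    manifest = {
        "config": config.to_dict(),
        "inputs": {name: _checksum(path) for name, path in inputs.items()},
        "n_reads": len(reads),
        "n_hits": len(hits),
        "n_arrays": len(arrays),
    }
    io.write_json(manifest, out_dir / "manifest.json")
    return out_dir
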