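# rttmatch

Mass-spectrometry-free identification of chromatographic peaks for
targeted analysis. Instead of warping or aligning chromatograms, the
detected peak retention times of a sample are treated as a trajectory
and compared *globally* against a library of trajectories measured (or
hybridized) under different instrument conditions. The candidate
assignment of peaks to target compounds whose trajectory best matches a
library trajectory — smallest mean squared residual (MSR) — is the
identification. The method handles arbitrary subsets of the target
list, flags non-target interferent peaks, and uses internal standards
to anchor and partition the search.

## How it works

1. **Library construction** — every library chromatogram contains all
   target compounds plus internal standards, so its retention times
   form a known trajectory (one per condition). Libraries can be
   expanded cheaply by linear hybridization of measured trajectories
   (midpoint and extrapolation formulas), widening the drift envelope
   without new measurements.
2. **Candidate enumeration** — every admissible assignment of sample
   peaks to target compounds is generated lazily, pruning by
   injectivity, strict elution-order preservation, an RT cutoff window
   (±Δt), and the regions delimited by internal-standard anchors.
3. **Screening and scoring** — trajectories are screened by the sum of
   squared internal-standard residuals, then each candidate is scored
   by MSR over standards plus assigned pairs; the global minimum wins.
4. **Interferent handling** — peaks matching no library RT within Δt
   are flagged outright; after matching, a peak whose squared residual
   is far above the pair's MSR (default: 2×) is relabeled interferent
   and the MSR renormalized over the remaining pairs.

## Command line

```bash
# simulate a drifted library + sample with known ground truth
rttmatch simulate --seed 7 --subset-size 8 --outdir demo/

# identify the sample against the library
rttmatch match --library demo/library.yaml --peaks demo/sample.csv \
    --delta-t 20 --out demo/report.tsv

# expand the library by hybridization (midpoint + both extrapolations)
rttmatch expand --library demo/library.yaml --out demo/expanded.yaml

# build a library from per-condition peak lists, extract apexes from a trace
rttmatch build-library --roster roster.yaml --out lib.yaml cond1.csv cond2.csv
rttmatch detect-peaks --min-prominence 1.0 --out peaks.csv trace.csv
```

Peak lists are CSV (`rt_seconds[,height][,standard_id]`); libraries and
rosters are YAML; match reports are TSV (rank, MSR, trajectory, one
column per peak with the compound id or `INTERFERENT`).

## Python API

```python
import rttmatch as rtt

library = rtt.read_library("library.yaml")
peaks = rtt.read_peak_list("sample.csv", library.roster)
cfg = rtt.MatchConfig(delta_t=15.0, allow_interferents=True)
results = rtt.match_sample(peaks, library, cfg)
print(results[0].assignment.mapping, results[0].msr)
```

Modules: `core` (types, validation, I/O), `peakdetect` (apex
extraction), `enumerate` (candidate generation), `match` (screening +
MSR ranking), `interferent` (flagging criteria), `hybridize` (library
expansion), `simulate` (synthetic drifted data), `cli`.

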