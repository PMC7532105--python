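# sequelkit

Quality control, read subsampling and read filtering for raw PacBio Sequel
sequence data (per-SMRTcell *subreads* and *scraps* files in SAM or BAM),
plus a deterministic synthetic-data generator used as the test substrate.

Read names follow the PacBio convention `movie/holeNumber/qStart_qEnd`,
where the coordinates are 0-based half-open positions on the polymerase
read (CLR).  Scraps records carry two one-character tags: `sz` (ZMW
classification: `N`ormal, `C`ontrol, `M`alformed, `S`entinel) and `sc`
(region type: `A`dapter, `B`arcode, `L`Q-region, `F`iltered).

## Concepts

* **CLR / polymerase read** — the full contiguous sequence from one ZMW;
  reconstructed here by coordinate arithmetic as the sum of all provided
  segment lengths.
* **Read groups** — QC works on up to four groups per SMRTcell:
  subreads, longest subreads (one per CLR), CLRs, and subedCLRs (CLRs
  containing at least one subread).  Without scraps files only subreads and
  longest subreads exist.  Only *normal* scraps (`sz == N`) enter the QC
  groups.
* **PSR** (polymerase-to-subread ratio) — total longest-subread bases /
  total subread bases.
* **ZOR** (ZMW-occupancy ratio) — number of subedCLRs / number of subreads.
* **Complete pass** — a subread flanked by adapter scraps on both sides.

## CLI

```sh
# generate two synthetic SMRTcells
sequelkit simulate --n-zmws 200 --seed 1 --cells 2 -o sim/

# QC: summary table + plot suite (intermediate is the default)
sequelkit qc --subreads sim/m54006_000001_000200.subreads.sam \
             --scraps   sim/m54006_000001_000200.scraps.sam \
             --plots full -o qc_out/

# subsampling: longest subread per CLR, or random CLRs
sequelkit subsample --subreads S.sam --longest -o out/
sequelkit subsample --subreads S.sam --scraps X.sam --random --fraction 0.25 --seed 7 -o out/

# filtering (requires scraps): min CLR length, complete passes, normal adapters
sequelkit filter --subreads S.sam --scraps X.sam \
                 --min-clr-length 1000 --full-pass --normal-adapters -o out/
```

Inputs can be repeated flags or manifests (`--subreads-list paths.txt`, one
path per line); subreads and scraps files are paired by movie name.
`--threads N` parallelises across SMRTcells only, so outputs are identical
for any thread count.  `--emit-bam` switches outputs to BAM.  Exit codes:
0 success, 2 usage error, 1 runtime error.

### QC outputs

`summary_statistics.tsv` has one row per (SMRTcell, read group) with
nReads, totalBases, mean, median, N50, L50, and — on the subreads row —
PSR and ZOR.  Plot suites (PDF): with scraps, full = A–J,
intermediate = A,C,G,H,I,J, basic = A,C; without scraps,
full = A,B,C,D,G,I,J, intermediate = A,C,G,I,J, basic = A,C.
Barplots (A N50, B L50, C total bases), boxplots (G subread lengths,
H subedCLR lengths, with N50s as blue diamonds) and ratio plots (I ZOR,
J PSR) show all cells in one file; read-length histograms (D) and
frequency plots (E subreads/subedCLR, F adapters/CLR) are written per
cell.  Every figure writes a `.tsv` sidecar of exactly the numbers it
plots — the extension point for custom plotting.  `-k` keeps the per-ZMW
intermediate tables (`<cell>.zmw_summary.tsv`).

## Layout

| module | contents |
| --- | --- |
| `sequelkit.records` | read-name parsing, record model, SAM/BAM reader/writer |
| `sequelkit.groups` | ZMW bundling, CLR lengths, the four read groups |
| `sequelkit.stats` | N50/L50/mean/median, PSR, ZOR, summary table |
| `sequelkit.report` | plot catalog A–J, suite selection, sidecars |
| `sequelkit.subsample` | longest-per-CLR and random-CLR subsampling |
| `sequelkit.filtering` | min CLR length, complete-pass, normal-adapter filters |
| `sequelkit.simulate` | seeded fixture generator + independent QC oracle |
| `sequelkit.cli` | `sequelkit {qc,subsample,filter,simulate}` |
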