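# Chunk index file format

A chunk index is a NumPy `.npz` archive (zip of `.npy` members) written by
`taxalign.fm_index.save_index` and read by `load_index`.  Loads are
validated: a missing or wrong magic string, an unsupported version, or a
truncated archive raise `IndexFormatError` — never a partial index.

| key | dtype | contents |
|---|---|---|
| `magic` | str scalar | `"TAXALIGN-FMIDX"` |
| `version` | int64 scalar | format version, currently `1` |
| `text` | int8, (n,) | encoded concatenated text: members joined by the separator symbol, terminal sentinel; alphabet codes `$`=0, `#`=1, `A`=2, `C`=3, `G`=4, `N`=5, `T`=6 |
| `bwt` | int8, (n,) | Burrows–Wheeler transform of `text` |
| `c_table` | int64, (7,) | cumulative symbol counts (backward-search C table) |
| `occ` | int64, (n+1, 7) | prefix rank table: `occ[i, c]` = occurrences of `c` in `bwt[:i]` |
| `boundaries` | int64, (m,) | start offset of each member sequence in `text` |
| `member_ids` | unicode, (m,) | member accessions, in chunk order |
| `member_lengths` | int64, (m,) | member lengths in bases |
| `sa_sample_rate` | int64 scalar | 1 = full suffix array |
| `suffix_array` | int64, (n,) | present when `sa_sample_rate == 1` |
| `sampled_rows` | int64 | BWT rows whose suffix-array value is a multiple of the rate (present when sampled) |
| `sampled_values` | int64 | the corresponding suffix-array values (present when sampled) |
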