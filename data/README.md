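# data

Optional external inputs for full-scale checks.

- `1y8k.pdb` — horse methaemoglobin tetramer, needed by the full-scale
  sizing test and by acceptance targets t6/t8. Not redistributed here;
  fetch it with:

  ```sh
  curl -o data/1y8k.pdb https://files.rcsb.org/download/1Y8K.pdb
  ```
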