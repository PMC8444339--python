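# JSON frequency schema

`nuclens.read_frequency_data` accepts, besides Molden frequency files, a
JSON document with the following keys:

| key              | type                 | meaning                                   |
|------------------|----------------------|-------------------------------------------|
| `symbols`        | list of str          | element symbols, one per atom              |
| `masses_amu`     | list of float, optional | per-atom masses; standard atomic weights used if absent |
| `coords_A`       | N×3 nested list      | equilibrium Cartesian coordinates in Å     |
| `freqs_cm1`      | list of float        | harmonic wavenumbers, negative = imaginary |
| `modes_cartesian`| n_modes×3N nested list | Cartesian displacement vectors, one row per mode (any normalization; they are mass-weighted and re-orthonormalized on read) |
| `label`          | str, optional        | free-text identifier                       |

`nuclens.write_frequency_json` emits exactly this schema, so a worked
example can be generated at any time:

```sh
nuclens fixtures --kind toymol --seed 1 --out example_freqs.json
```

which writes the bent-triatomic toy (3 atoms, 3 modes).  Example excerpt:

```json
{
 "symbols": ["O", "H", "H"],
 "masses_amu": [15.999, 1.008, 1.008],
 "coords_A": [[0.0, 0.0, 0.0], [0.757, 0.0, 0.586], [-0.757, 0.0, 0.586]],
 "freqs_cm1": [1606.42, 2871.96, 2912.76],
 "modes_cartesian": [[0.0, "..."], ["..."], ["..."]]
}
```

Validation on read: mode count must imply 5 or 6 projected rigid modes
(else an error); mass-weighted mode vectors must be orthonormalizable with
Gram deviation below 10⁻³ (else an error reporting the deviation); a mode
count disagreeing with the geometry's linearity is accepted with a warning.
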