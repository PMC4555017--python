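# drivedaq

Software data model for a **direct-to-drive neural data acquisition (DAQ)
module**: an FPGA-based recorder that digitizes 1024 extracellular channels
at 30 kS/s, 16-bit, and writes the stream straight to a SATA drive — no
computer, no file system — while mirroring data over Ethernet as UDP
datagrams.

The package is for electrophysiologists and data engineers who need to
**read, write, validate, simulate and merge** sessions in this record
format: the exact byte-level codec, the closed-form rate/capacity budget,
a synthetic session generator, the post-experiment integrity validator, a
datagram packetizer with loss simulation, and a multi-module clock
synchronization/merge simulator.

## The data model

One **complete module sample** per 30 kHz tick:

| section  | bytes | content |
|----------|------:|---------|
| metadata | 20    | experiment id (u64, UNIX UTC), module id (u32, MAC-derived), sample index (u32, wraps at 2³²), chip-live mask (u32) |
| neural   | 2048  | 1024 × u16, chip-major (32 chips × 32 channels) |
| aux      | 192   | 96 × u16, 3 per chip; 16 GPIO lines latched at 2 kHz into a designated slot |
| padding  | 1836  | zeros, bringing the record to a fixed 4096 bytes |

All integers little-endian. Records are written sequentially in blocks of
128 (512 KiB). The arithmetic that follows is exact:

- total rate: 4096 B × 30 000 /s = **122.88 MB/s** (fits SATA 1's 187.5 MB/s)
- channel payload: 2240 B × 30 000 /s = 67.2 MB/s; metadata is 20/2240 = **0.9 %** of it
- padding is 1836/4096 = **44.8 %** of the record — headroom for **831** additional neural channels (with proportional aux + metadata)
- one amplifier chip: 35 words × 16 bit × 30 000 /s = **16.8 Mbit/s**; 32 chips = **1120 channels**
- the 32-bit sample counter rolls over after **39 h**; a 512 GB (decimal) drive holds 125 000 000 samples ≈ **70 min**

## Worked example

```sh
$ drivedaq generate --samples 1000 --seed 7 --chips 1 -o session.dat
wrote 1000 samples (4096000 bytes) to session.dat

$ drivedaq validate session.dat
records:        1000
experiment_id:  1441065600
module_id:      3670081518
index range:    0 .. 999 (raw)
                0 .. 999 (unwrapped)
result:         PASS
```

1000 samples occupy exactly 1000 × 4096 = 4 096 000 bytes; the validator
confirms the identifiers never change, the sample index increments by
exactly one (a 2³² rollover is not a skip), and the padding is all zeros
— the same checks run against the real hardware's drives after an
experiment. Inject a fault and it is located:

```sh
$ head -c 4091904 session.dat > truncated.dat   # chop to 999 records + 4 KB missing
$ drivedaq validate truncated.dat --expected-bytes 4096000 ; echo "exit $?"
...
result:         FAIL (1 errors)
  [SIZE_MISMATCH] record 999: 999 records found, expected 1000 from 4096000 bytes
exit 1
```

The budget table, channel extraction, datagram simulation and
multi-module merging are the remaining subcommands:

```sh
drivedaq budget --drive-gb 512 --json     # every figure above, computed
drivedaq extract session.dat --channels 0,5,1024 --csv out.csv
drivedaq stream-sim --session session.dat --loss 0.1 --seed 3 -o packets.bin
drivedaq stream-sim --replay packets.bin  # reassembly + gap report
drivedaq merge moduleA.dat moduleB.dat -o combined
```

## Library surface

```python
from drivedaq import SimConfig, generate_session, write_session, validate_session

cfg = SimConfig(n_chips=4, n_units=8, duration_samples=30_000, seed=1)
with open("session.dat", "wb") as fh:
    write_session(generate_session(cfg), fh)
report = validate_session("session.dat")
assert report.passed
```

Modules: `drivedaq.layout` (record constants and containers),
`drivedaq.codec` (encode/decode, session I/O, O(1) seek, index
unwrapping, channel extraction/export), `drivedaq.budget`,
`drivedaq.simulate` (+ ground truth), `drivedaq.validate`,
`drivedaq.netstream`, `drivedaq.syncmerge`, `drivedaq.analysis`,
`drivedaq.cli`. See `docs/methods.md` for the models, conventions and
their rationale.
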