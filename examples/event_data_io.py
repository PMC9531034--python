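"""Binning event streams and reading neuromorphic file formats.

Events are (time, channel) pairs binned into half-open-left windows;
several events may stack in one bin — the integer multiplicity that
binary-spike pipelines lose.  The same binning backs the readers for
the 5-byte event-camera format and the spiking-cochlea HDF5 layout.
"""

import os
import tempfile

from mapsnn import bin_events, read_nmnist_file, write_nmnist_file

grid = bin_events([(4.5, 0), (4.9, 0), (12.0, 1), (15.0, 1)],
                  T=20.0, dt=5.0, n_channels=2)
print("Binned counts (2 channels x 4 bins of 5 ms):")
print(grid.counts)
print("Two events stacked in bin 0 of channel 0; the boundary event at "
      "exactly t=15 ms joins bin 2 (windows are (k dt, (k+1) dt]).\n")

# round-trip a tiny synthetic recording through the event-camera format
events = [(3, 7, 0, 12.0), (3, 7, 1, 12.5), (3, 7, 0, 13.0), (33, 0, 0, 150.0)]
with tempfile.TemporaryDirectory() as d:
    path = os.path.join(d, "digit.bin")
    write_nmnist_file(path, events)
    back = read_nmnist_file(path)
print(f"Event-camera round-trip: wrote {len(events)} events, read back a "
      f"{back.counts.shape[0]}-channel x {back.counts.shape[1]}-bin grid "
      f"holding {back.counts.sum()} events (2 polarities x 34 x 34 pixels, "
      "15 bins of 20 ms).")
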