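"""Glibc allocator tuning for training workloads.

Training churns many short-lived multi-megabyte activation buffers.  With
glibc defaults these are mmap'd and returned to the kernel on free, so every
minibatch re-faults its pages; on kernels where minor faults are expensive
this dominates run time.  Raising the mmap and trim thresholds keeps freed
blocks in the heap for reuse.  No-op on non-glibc platforms.
"""

from __future__ import annotations

import ctypes
import ctypes.util

_M_TRIM_THRESHOLD = -1
_M_MMAP_THRESHOLD = -3


def tune_allocator() -> bool:
    try:
        libc = ctypes.CDLL(ctypes.util.find_library("c") or "libc.so.6",
                           use_errno=True)
        mallopt = libc.mallopt
    except (OSError, AttributeError):
        return False
    ok = mallopt(_M_MMAP_THRESHOLD, 1 << 30)
    ok &= mallopt(_M_TRIM_THRESHOLD, (1 << 31) - 1)
    return bool(ok)


TUNED = tune_allocator()
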