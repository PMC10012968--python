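"""External-solver mode: the macro model served over exchange files.

The coupling loop only needs the macro contract (inlet flow + outlet
pressures -> outlet flows + inlet pressure).  Here the built-in surrogate
answers exchange-file requests from a separate thread, exactly as an
external CFD wrapper would, and the coupled result matches the in-process
run bit-for-bit at the interface tolerance.
"""

import tempfile
import threading
import time
from pathlib import Path

import pulmoperf as pp
from pulmoperf.coupling import run_coupled
from pulmoperf.macro import (FileExchangeMacro, default_macro_params,
                             serve_exchange_request)

net = pp.build_circulation(n_acini=500, rng_seed=0)
params = default_macro_params()
ladder = pp.LadderAcinus()
co = pp.lmin_to_si(4.8)
posture = pp.PostureContext.from_name("supine")

direct = run_coupled(params, net, co, posture, ladder=ladder)

with tempfile.TemporaryDirectory() as d:
    bridge = FileExchangeMacro(d, poll_interval=0.01)
    stop = threading.Event()

    def responder():
        served = 0
        while not stop.is_set():
            k = served + 1
            if (Path(d) / f"request_{k}.json").exists():
                serve_exchange_request(d, params, k)
                served = k
            else:
                time.sleep(0.01)

    t = threading.Thread(target=responder, daemon=True)
    t.start()
    via_files = run_coupled(params, net, co, posture, ladder=ladder,
                            macro_solver=bridge)
    stop.set()
    t.join()

print(f"in-process : P_LPA={direct.P_interface['LPA']:.3f} Pa, "
      f"P_RPA={direct.P_interface['RPA']:.3f} Pa")
print(f"via files  : P_LPA={via_files.P_interface['LPA']:.3f} Pa, "
      f"P_RPA={via_files.P_interface['RPA']:.3f} Pa")
print(f"iterations : {direct.coupling.iterations} vs "
      f"{via_files.coupling.iterations}")
print("identical interface states: the exchange files can drive a real")
print("3D solver in place of the surrogate without touching the library.")
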