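"""Packaged sanitizer fixture suites.

``ADVERSARIAL`` pairs each script with the rule_id its worst violation
must trigger; the sanitizer must reject every one (zero false
negatives).  ``BENIGN`` scripts stay within the analytics contract and
must all pass (zero false positives) — the template-generated scripts
are checked separately on top of these.

All scripts are synthetic, written for this suite.
"""

ADVERSARIAL: list[tuple[str, str]] = [
    # --- parse errors -----------------------------------------------------
    ("parse_error", "def broken(:\n    pass\n"),
    ("parse_error", "import pandas as\n"),
    # --- disallowed imports ----------------------------------------------
    ("import_violation", "import requests_cache\nprint('hi')\n"),
    ("import_violation", "from scipy import stats\nprint(stats)\n"),
    ("import_violation", "from . import secrets_module\n"),
    # --- network ----------------------------------------------------------
    ("network", "import socket\ns = socket.socket()\n"),
    ("network", "import urllib.request\nurllib.request.urlopen('http://x.test')\n"),
    ("network", "from http.client import HTTPConnection\n"),
    ("network", "import requests\nrequests.get('http://x.test')\n"),
    # --- process spawning ---------------------------------------------------
    ("process_spawn", "import subprocess\nsubprocess.run(['ls'])\n"),
    ("process_spawn", "import multiprocessing\nmultiprocessing.Pool(2)\n"),
    ("process_spawn", "from subprocess import Popen\nPopen(['ls'])\n"),
    ("process_spawn", "import os\nos.system('id')\n"),
    # --- filesystem access -------------------------------------------------
    ("fs_access", "data = open('/etc/passwd').read()\nprint(data)\n"),
    ("fs_access", "import shutil\nshutil.rmtree('/tmp/x')\n"),
    ("fs_access", "import pandas as pd\npd.read_csv('/etc/hosts')\n"),
    ("fs_access", "import pathlib\npathlib.Path('x').write_text('y')\n"),
    ("fs_access", "import glob\nprint(glob.glob('/home/*'))\n"),
    # --- dynamic evaluation / reflection ------------------------------------
    ("dynamic_eval", "eval('1 + 1')\n"),
    ("dynamic_eval", "exec('import os')\n"),
    ("dynamic_eval", "__import__('os')\n"),
    ("dynamic_eval", "import pickle\npickle.loads(b'')\n"),
    ("dynamic_eval", "f = getattr(str, 'format')\n"),
    # --- environment / interpreter internals --------------------------------
    ("env_access", "import sys\nprint(sys.modules.keys())\n"),
    ("env_access", "import math\nprint(environ)\n"),
    ("env_access", "import sys\nsys._getframe(0)\n"),
    # --- dunder access -------------------------------------------------------
    ("dunder_access", "x = (1).__class__.__bases__\n"),
    ("dunder_access", "import pandas as pd\npd.__loader__\n"),
    ("dunder_access", "__builtins__['print']('x')\n"),
]

BENIGN: list[str] = [
    # minimal numeric work, no IO at all
    "import math\nprint(math.sqrt(2.0))\n",
    # tabular summary via the injected argv contract
    (
        "import sys\nimport pandas as pd\n"
        "df = pd.read_csv(sys.argv[1])\n"
        "print(df.shape[0])\n"
    ),
    # numpy arithmetic
    "import numpy as np\nprint(np.arange(5).sum())\n",
    # writing an artifact through the injected output directory
    (
        "import sys\nimport pandas as pd\n"
        "df = pd.read_csv(sys.argv[1])\n"
        "df.head().to_csv(sys.argv[2] + '/head.csv', index=False)\n"
    ),
]
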