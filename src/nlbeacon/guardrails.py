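"""Guard-railed analytics: template code generation, static sanitization,
and sandboxed execution with captured streams.

Any analytics script — template-generated or user-edited — passes through
two independent layers before its output is trusted:

1. :func:`sanitize` walks the full syntax tree and rejects scripts that
   import outside the allowlist, touch the filesystem beyond the injected
   input path and output directory, open sockets, spawn processes, use
   dynamic evaluation/reflection, read the environment or interpreter
   internals, or access double-underscore names.  The whole script is
   rejected (with every violation reported) rather than rewritten;
   excision risks semantically broken code, and the user can edit and
   resubmit.
2. :func:`run_sandboxed` executes the script in a separate process with a
   fresh working directory, CPU/memory/wall limits, and an
   interpreter-level shim that disables sockets and process spawning and
   confines file access — so even a script that skipped sanitization
   (defense in depth) cannot reach the network or files outside its
   directory.  Stdout and stderr are captured verbatim for the user.

Scripts read exactly one tabular input (CSV with header) and write
figure/table artifacts to exactly one output directory, both injected as
``sys.argv`` parameters.  Cohort data and session state live in the
parent process and are unreachable from the sandbox; by construction no
operation in this module accepts an extraction backend.
"""

from __future__ import annotations

import ast
import subprocess
import sys
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

ANALYTICS_KINDS = ("pie_chart", "bar_chart", "grouped_count_table", "ratio_table")

#: Import roots allowed in analytics scripts: tabular + plotting + math
#: only.  Ships as config — deployers may extend it.
DEFAULT_IMPORT_ALLOWLIST = frozenset(
    {"pandas", "numpy", "matplotlib", "math", "statistics", "sys"}
)


class GenerationError(Exception):
    """Unknown analytics kind or column; message lists available columns."""


class SanitizationError(Exception):
    """Raised when execution is requested for code that is not clean."""

    def __init__(self, report: "SanitizeReport"):
        self.report = report
        super().__init__(
            "code rejected by sanitizer: "
            + "; ".join(v.rule_id for v in report.violations)
        )


@dataclass
class AnalyticsRequest:
    kind: str
    group_field: str
    value_field: str | tuple[str, str] | None = None
    title: str = ""


@dataclass
class Violation:
    rule_id: str
    description: str
    line: int
    col: int


@dataclass
class SanitizeReport:
    verdict: str  # "clean" | "rejected"
    violations: list[Violation] = field(default_factory=list)


@dataclass
class SandboxLimits:
    cpu_seconds: int = 10
    memory_bytes: int = 4 * 2**30
    wall_seconds: int = 30


@dataclass
class ExecutionResult:
    status: str  # "ok" | "error" | "timeout" | "killed"
    stdout: str
    stderr: str
    artifacts: list[str] = field(default_factory=list)
    returncode: int | None = None


# ---------------------------------------------------------------------------
# template generation

_PRELUDE = '''\
import sys
import pandas as pd
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

table_path = sys.argv[1]
out_dir = sys.argv[2]
df = pd.read_csv(table_path)
'''

_TEMPLATES = {
    "pie_chart": '''\
counts = df[{group!r}].value_counts().sort_index()
fig, ax = plt.subplots(figsize=(5, 5))
ax.pie(counts.to_numpy(), labels=[str(x) for x in counts.index], autopct="%1.1f%%")
ax.set_title({title!r})
fig.savefig(out_dir + "/pie_chart.png", dpi=150)
for label, n in counts.items():
    print(label, int(n))
''',
    "bar_chart": '''\
series = df.groupby({group!r})[{value!r}].mean().sort_index()
fig, ax = plt.subplots(figsize=(6, 4))
ax.bar([str(x) for x in series.index], series.to_numpy())
ax.set_xlabel({group!r})
ax.set_ylabel("mean " + {value!r})
ax.set_title({title!r})
fig.savefig(out_dir + "/bar_chart.png", dpi=150)
for label, v in series.items():
    print(label, float(v))
''',
    "grouped_count_table": '''\
counts = df.groupby({group!r}).size().rename("count").reset_index()
counts.to_csv(out_dir + "/grouped_counts.csv", index=False)
print(counts.to_string(index=False))
''',
    "ratio_table": '''\
rates = df.groupby({group!r})[[{a!r}, {b!r}]].mean()
rates["ratio"] = rates[{a!r}] / rates[{b!r}]
table = rates.reset_index()
table.to_csv(out_dir + "/ratio_table.csv", index=False)
print(table.to_string(index=False))
''',
}

_COUNT_BAR_TEMPLATE = '''\
series = df[{group!r}].value_counts().sort_index()
fig, ax = plt.subplots(figsize=(6, 4))
ax.bar([str(x) for x in series.index], series.to_numpy())
ax.set_xlabel({group!r})
ax.set_ylabel("count")
ax.set_title({title!r})
fig.savefig(out_dir + "/bar_chart.png", dpi=150)
for label, v in series.items():
    print(label, int(v))
'''


def generate_analysis(req: AnalyticsRequest, schema: list[str]) -> str:
    """Emit a standalone analytics script from a vetted template.

    The script reads one CSV (``sys.argv[1]``) and writes artifacts to
    one output directory (``sys.argv[2]``).  Generated code always passes
    :func:`sanitize`.
    """
    if req.kind not in ANALYTICS_KINDS:
        raise GenerationError(
            f"unknown analytics kind {req.kind!r}; available: {ANALYTICS_KINDS}"
        )
    if req.group_field not in schema:
        raise GenerationError(
            f"column {req.group_field!r} not in table; available columns: "
            f"{sorted(schema)}"
        )
    title = req.title or f"{req.kind} of {req.group_field}"
    if req.kind == "pie_chart":
        body = _TEMPLATES["pie_chart"].format(group=req.group_field, title=title)
    elif req.kind == "bar_chart":
        if req.value_field is None:
            body = _COUNT_BAR_TEMPLATE.format(group=req.group_field, title=title)
        else:
            value = req.value_field
            if not isinstance(value, str) or value not in schema:
                raise GenerationError(
                    f"value column {value!r} not in table; available columns: "
                    f"{sorted(schema)}"
                )
            body = _TEMPLATES["bar_chart"].format(
                group=req.group_field, value=value, title=title
            )
    elif req.kind == "grouped_count_table":
        body = _TEMPLATES["grouped_count_table"].format(group=req.group_field)
    else:  # ratio_table
        if (
            not isinstance(req.value_field, (tuple, list))
            or len(req.value_field) != 2
        ):
            raise GenerationError(
                "ratio_table needs value_field = (numerator_column, "
                f"denominator_column); available columns: {sorted(schema)}"
            )
        a, b = req.value_field
        for col in (a, b):
            if col not in schema:
                raise GenerationError(
                    f"column {col!r} not in table; available columns: "
                    f"{sorted(schema)}"
                )
        body = _TEMPLATES["ratio_table"].format(group=req.group_field, a=a, b=b)
    return _PRELUDE + "\n" + body


# ---------------------------------------------------------------------------
# static sanitization

_NETWORK_MODULES = {
    "socket", "ssl", "urllib", "http", "requests", "ftplib", "smtplib",
    "telnetlib", "poplib", "imaplib", "xmlrpc", "asyncio",
}
_PROCESS_MODULES = {"subprocess", "multiprocessing", "pty", "_posixsubprocess"}
_FS_MODULES = {
    "os", "pathlib", "shutil", "io", "tempfile", "glob", "fileinput",
    "zipfile", "tarfile", "sqlite3",
}
_DYNAMIC_MODULES = {
    "importlib", "ctypes", "pickle", "marshal", "code", "inspect", "types",
    "builtins", "gc",
}

_DYNAMIC_BUILTINS = {
    "eval", "exec", "compile", "__import__", "globals", "locals", "vars",
    "getattr", "setattr", "delattr", "breakpoint",
}
_PROCESS_ATTRS = {
    "system", "popen", "fork", "execv", "execve", "spawnl", "spawnv",
    "Popen", "check_output", "check_call",
}
_NETWORK_ATTRS = {"socket", "create_connection", "urlopen", "getaddrinfo"}
_ENV_NAMES = {"environ", "getenv", "putenv", "unsetenv", "environb"}
_INTERP_ATTRS = {
    "modules", "_getframe", "settrace", "setprofile", "meta_path",
    "path_hooks", "implementation",
}
_LITERAL_PATH_IO = {
    "open", "read_csv", "read_table", "read_json", "read_excel",
    "read_parquet", "to_csv", "to_json", "to_excel", "savefig",
    "read_text", "write_text", "read_bytes", "write_bytes",
}


def _classify_import(root: str, allowlist: frozenset[str]) -> str | None:
    if root in allowlist:
        return None
    if root in _NETWORK_MODULES:
        return "network"
    if root in _PROCESS_MODULES:
        return "process_spawn"
    if root in _FS_MODULES:
        return "fs_access"
    if root in _DYNAMIC_MODULES:
        return "dynamic_eval"
    return "import_violation"


class _SanitizeVisitor(ast.NodeVisitor):
    def __init__(self, allowlist: frozenset[str]):
        self.allowlist = allowlist
        self.violations: list[Violation] = []

    def _flag(self, node: ast.AST, rule_id: str, description: str) -> None:
        self.violations.append(
            Violation(
                rule_id=rule_id,
                description=description,
                line=getattr(node, "lineno", 0),
                col=getattr(node, "col_offset", 0),
            )
        )

    def visit_Import(self, node: ast.Import) -> None:
        for alias in node.names:
            root = alias.name.split(".")[0]
            rule = _classify_import(root, self.allowlist)
            if rule:
                self._flag(node, rule, f"import of {alias.name!r} is not allowed")
        self.generic_visit(node)

    def visit_ImportFrom(self, node: ast.ImportFrom) -> None:
        root = (node.module or "").split(".")[0]
        if node.level or not root:
            self._flag(node, "import_violation", "relative import is not allowed")
        else:
            rule = _classify_import(root, self.allowlist)
            if rule:
                self._flag(node, rule, f"import from {node.module!r} is not allowed")
        self.generic_visit(node)

    def visit_Call(self, node: ast.Call) -> None:
        func = node.func
        name = None
        if isinstance(func, ast.Name):
            name = func.id
            if name in _DYNAMIC_BUILTINS:
                self._flag(node, "dynamic_eval", f"call to {name}() is not allowed")
            elif name == "open":
                self._flag(
                    node, "fs_access", "direct open() is not allowed; scripts "
                    "read only the injected input path"
                )
        elif isinstance(func, ast.Attribute):
            name = func.attr
            if name in _PROCESS_ATTRS:
                self._flag(node, "process_spawn", f".{name}() spawns a process")
            elif name in _NETWORK_ATTRS:
                self._flag(node, "network", f".{name}() opens a network channel")
        if name in _LITERAL_PATH_IO:
            for arg in node.args[:1]:
                if isinstance(arg, ast.Constant) and isinstance(arg.value, str):
                    self._flag(
                        node,
                        "fs_access",
                        f"{name}() with a literal path {arg.value!r}; only the "
                        "injected input path and output directory may be used",
                    )
        self.generic_visit(node)

    def visit_Attribute(self, node: ast.Attribute) -> None:
        if node.attr.startswith("__"):
            self._flag(node, "dunder_access", f"access to {node.attr!r}")
        elif node.attr in _ENV_NAMES:
            self._flag(node, "env_access", f"environment access via .{node.attr}")
        elif node.attr in _INTERP_ATTRS:
            self._flag(
                node, "env_access", f"interpreter internals via .{node.attr}"
            )
        self.generic_visit(node)

    def visit_Name(self, node: ast.Name) -> None:
        if node.id.startswith("__"):
            self._flag(node, "dunder_access", f"access to name {node.id!r}")
        elif node.id in _ENV_NAMES:
            self._flag(node, "env_access", f"environment access via {node.id}")
        self.generic_visit(node)


def sanitize(
    code: str, allowlist: frozenset[str] = DEFAULT_IMPORT_ALLOWLIST
) -> SanitizeReport:
    """Static analysis of analytics code; reject-whole, every violation listed."""
    try:
        tree = ast.parse(code)
    except SyntaxError as e:
        return SanitizeReport(
            "rejected",
            [Violation("parse_error", str(e), e.lineno or 0, e.offset or 0)],
        )
    visitor = _SanitizeVisitor(allowlist)
    visitor.visit(tree)
    if visitor.violations:
        return SanitizeReport("rejected", visitor.violations)
    return SanitizeReport("clean")


# ---------------------------------------------------------------------------
# sandboxed execution

_RUNNER_SOURCE = '''\
"""Sandbox runner: installs interpreter-level guards, then runs the script.

argv: runner.py <script> <table> <out_dir> <cpu_seconds> <memory_bytes>
"""
import builtins
import io
import os
import resource
import sys
import traceback
import types

script, table, out_dir, cpu_s, mem_b = sys.argv[1:6]
cpu_s, mem_b = int(cpu_s), int(mem_b)
work_dir = os.path.realpath(os.getcwd())

resource.setrlimit(resource.RLIMIT_CPU, (cpu_s, cpu_s + 1))
if mem_b > 0:
    resource.setrlimit(resource.RLIMIT_AS, (mem_b, mem_b))

_read_roots = [
    os.path.realpath(p)
    for p in (sys.prefix, sys.base_prefix, work_dir, table, out_dir)
]
_write_roots = [os.path.realpath(p) for p in (out_dir, work_dir)]
_real_open = builtins.open


def _inside(path, roots):
    return any(path == r or path.startswith(r.rstrip("/") + "/") for r in roots)


def _check(path, mode):
    if isinstance(path, int):
        return
    p = os.path.realpath(os.fspath(path))
    writing = any(c in str(mode) for c in "wax+")
    roots = _write_roots if writing else _read_roots + _write_roots
    if not _inside(p, roots):
        raise PermissionError("sandbox: access to %r denied" % (p,))


def _guarded_open(file, mode="r", *a, **k):
    _check(file, mode)
    return _real_open(file, mode, *a, **k)


builtins.open = _guarded_open
io.open = _guarded_open


def _deny(*a, **k):
    raise PermissionError("sandbox: capability disabled")


import socket as _socket

for _name in ("socket", "create_connection", "socketpair", "getaddrinfo",
              "gethostbyname", "create_server"):
    setattr(_socket, _name, _deny)

# Replace subprocess with a stub: real exception classes stay (libraries
# name them in except clauses), every callable becomes a denial.
import subprocess as _real_subprocess

_stub = types.ModuleType("subprocess")
for _name in dir(_real_subprocess):
    _obj = getattr(_real_subprocess, _name)
    if isinstance(_obj, type) and issubclass(_obj, BaseException):
        setattr(_stub, _name, _obj)
_stub.__getattr__ = lambda name: _deny
sys.modules["subprocess"] = _stub

for _name in ("system", "popen", "fork", "forkpty", "execv", "execve",
              "spawnl", "spawnv", "posix_spawn", "posix_spawnp"):
    if hasattr(os, _name):
        setattr(os, _name, _deny)

with _real_open(script, "r", encoding="utf-8") as fh:
    _code = fh.read()
sys.argv = [script, table, out_dir]
_globals = {"__name__": "__main__", "__file__": script, "__builtins__": builtins}
try:
    exec(compile(_code, script, "exec"), _globals)
except SystemExit:
    raise
except BaseException:
    traceback.print_exc()
    sys.exit(1)
'''


def run_sandboxed(
    code: str,
    table: str | Path,
    limits: SandboxLimits | None = None,
    output_dir: str | Path | None = None,
    *,
    skip_sanitize: bool = False,
) -> ExecutionResult:
    """Execute analytics code in a fresh, guarded subprocess.

    Requires ``sanitize(code)`` to be clean unless ``skip_sanitize`` is
    set (a testing hook for exercising the second defense layer on its
    own).  Streams are captured verbatim; artifacts are the files the
    script left in its output directory.
    """
    if not skip_sanitize:
        report = sanitize(code)
        if report.verdict != "clean":
            raise SanitizationError(report)
    limits = limits or SandboxLimits()

    work = Path(tempfile.mkdtemp(prefix="nlbeacon-sandbox-"))
    out_dir = Path(output_dir) if output_dir is not None else work / "out"
    out_dir.mkdir(parents=True, exist_ok=True)
    (work / "mpl").mkdir()
    script = work / "script.py"
    script.write_text(code, encoding="utf-8")
    runner = work / "runner.py"
    runner.write_text(_RUNNER_SOURCE, encoding="utf-8")

    env = {
        "PATH": "/usr/bin:/bin",
        "HOME": str(work),
        "TMPDIR": str(work),
        "MPLCONFIGDIR": str(work / "mpl"),
        "LANG": "C.UTF-8",
    }
    cmd = [
        sys.executable,
        "-I",
        str(runner),
        str(script),
        str(Path(table).resolve()),
        str(out_dir.resolve()),
        str(limits.cpu_seconds),
        str(limits.memory_bytes),
    ]
    try:
        proc = subprocess.run(
            cmd,
            cwd=work,
            env=env,
            capture_output=True,
            text=True,
            timeout=limits.wall_seconds,
        )
        stdout, stderr, returncode = proc.stdout, proc.stderr, proc.returncode
    except subprocess.TimeoutExpired as e:
        stdout = e.stdout.decode() if isinstance(e.stdout, bytes) else (e.stdout or "")
        stderr = e.stderr.decode() if isinstance(e.stderr, bytes) else (e.stderr or "")
        return ExecutionResult(
            status="timeout",
            stdout=stdout,
            stderr=stderr,
            artifacts=_list_artifacts(out_dir),
        )

    if returncode == 0:
        status = "ok"
    elif returncode < 0:
        status = "killed"
    else:
        status = "error"
    return ExecutionResult(
        status=status,
        stdout=stdout,
        stderr=stderr,
        artifacts=_list_artifacts(out_dir),
        returncode=returncode,
    )


def _list_artifacts(out_dir: Path) -> list[str]:
    return sorted(str(p) for p in out_dir.iterdir() if p.is_file())
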