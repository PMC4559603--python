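"""Execution backends: the session contract, an in-process mock, and an
R subprocess backend.

A backend is any session provider implementing the small contract the
engine needs: set a named value, evaluate one code unit returning its text
output, fetch a named value back, cancel, close. Setting then fetching a
name returns an equal value; evaluation is sequential within a session.

Two implementations ship:

* :class:`MockBackend` — an in-process environment with tiny
  assignment/expression semantics, used by unit tests and the CLI's dry
  runs. By default it is lenient: a line it cannot interpret is echoed into
  the transcript as a no-op, so real R scripts can be smoke-run without an
  R installation. ``strict=True`` raises instead.

* :class:`RBackend` — drives a real R interpreter as an ``Rscript``
  subprocess over a length-prefixed UTF-8 frame protocol with JSON payloads
  (tabular values travel column-major). One session per running app.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import BackendError

__all__ = ["Backend", "BackendValue", "BackendError", "MockBackend", "RBackend"]


@dataclass
class BackendValue:
    """A typed value crossing the session boundary.

    ``kind`` is one of integer, numeric, logical, character (scalars),
    vector (1-D numeric), or table (a DataFrame).
    """

    kind: str
    value: Any

    _KINDS = ("integer", "numeric", "logical", "character", "vector", "table")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown backend value kind {self.kind!r}")


class Backend(ABC):
    """Session contract required by the engine."""

    @abstractmethod
    def open(self) -> None: ...

    @abstractmethod
    def close(self) -> None: ...

    @abstractmethod
    def set_value(self, name: str, value: BackendValue) -> None: ...

    @abstractmethod
    def evaluate(self, code: str) -> str:
        """Run one code unit; return its text output or raise BackendError."""

    @abstractmethod
    def fetch(self, name: str):
        """Return the session value bound to ``name`` (BackendError if absent)."""

    def cancel(self) -> None:  # default: nothing to interrupt
        pass

    def __enter__(self):
        self.open()
        return self

    def __exit__(self, *exc):
        self.close()
        return False


# ---------------------------------------------------------------------------
# Mock backend


def _unwrap(value: BackendValue):
    if value.kind == "table":
        df = value.value
        return df.copy() if isinstance(df, pd.DataFrame) else pd.DataFrame(df)
    if value.kind == "vector":
        return list(np.asarray(value.value, dtype=float))
    return value.value


class MockBackend(Backend):
    """In-process session with assignment/expression semantics.

    Each line of a unit is interpreted as either ``name <- expression`` (or
    ``name = expression``) or a bare expression whose value is echoed to the
    output, mirroring an interactive console. Expressions are evaluated in
    the session environment extended with a small function table; callables
    registered via ``functions`` let tests script arbitrary behavior (e.g.
    a correlation routine). Lenient mode turns uninterpretable lines into
    no-ops so shipped R scripts can be smoke-run.
    """

    def __init__(self, functions: dict | None = None, strict: bool = False):
        self.strict = strict
        self.env: dict[str, Any] = {}
        self.functions: dict[str, Any] = {
            "abs": abs,
            "min": min,
            "max": max,
            "sum": sum,
            "len": len,
            "log2": np.log2,
            "log10": np.log10,
            "log": np.log,
            "sqrt": np.sqrt,
            "exp": np.exp,
            "c": lambda *a: list(a),
            "nrow": lambda df: len(df),
            "ncol": lambda df: df.shape[1],
            "fail": self._fail,
        }
        if functions:
            self.functions.update(functions)
        self._open = False

    @staticmethod
    def _fail(message: str = "scripted failure"):
        raise RuntimeError(message)

    def open(self) -> None:
        self._open = True

    def close(self) -> None:
        self._open = False

    def set_value(self, name: str, value: BackendValue) -> None:
        self.env[name] = _unwrap(value)

    def fetch(self, name: str):
        if name not in self.env:
            raise BackendError(f"no session variable named {name!r}")
        return self.env[name]

    def _eval_expr(self, expr: str):
        scope = dict(self.functions)
        scope.update(self.env)
        return eval(expr, {"__builtins__": {}}, scope)  # noqa: S307 - sandboxed scope

    def evaluate(self, code: str) -> str:
        out: list[str] = []
        for line in code.splitlines() or [""]:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            target = None
            expr = stripped
            for op in ("<-", "="):
                if op in stripped:
                    lhs, rhs = stripped.split(op, 1)
                    if lhs.strip().isidentifier() and not rhs.lstrip().startswith("="):
                        target, expr = lhs.strip(), rhs.strip()
                    break
            try:
                value = self._eval_expr(expr)
            except RuntimeError as exc:  # scripted failure
                raise BackendError(str(exc), output="\n".join(out + [f"Error: {exc}"]))
            except Exception as exc:
                if self.strict:
                    raise BackendError(
                        f"cannot interpret line {stripped!r}: {exc}",
                        output="\n".join(out + [f"Error: {exc}"]),
                    )
                out.append(f"[ignored] {stripped}")
                continue
            if target is not None:
                self.env[target] = value
            else:
                out.append(repr(value))
        return "\n".join(out)


# ---------------------------------------------------------------------------
# R subprocess backend

_R_DRIVER = r"""
suppressWarnings(suppressMessages(library(jsonlite)))
options(device = function(...) pdf(file = NULL))  # headless: no Rplots.pdf
fin <- file("stdin", "rb")

read_frame <- function() {
  hdr <- readLines(fin, n = 1, warn = FALSE)
  if (length(hdr) == 0 || !nzchar(hdr)) return(NULL)
  n <- as.integer(hdr)
  if (is.na(n)) return(NULL)
  body <- readChar(fin, n, useBytes = TRUE)
  Encoding(body) <- "UTF-8"
  body
}

send <- function(status, text) {
  raw <- charToRaw(enc2utf8(text))
  cat(sprintf("%s %d\n", status, length(raw)))
  cat(text, sep = "")
  cat("\n")
  flush(stdout())
}

decode_value <- function(obj) {
  switch(obj$kind,
    integer   = as.integer(obj$value),
    numeric   = as.numeric(obj$value),
    logical   = as.logical(obj$value),
    character = as.character(obj$value),
    vector    = as.numeric(obj$value),
    table     = {
      d <- lapply(obj$data, function(col) if (is.list(col)) unlist(lapply(col, function(x) if (is.null(x)) NA else x)) else col)
      df <- as.data.frame(d, stringsAsFactors = FALSE, optional = TRUE)
      df[, unlist(obj$columns), drop = FALSE]
    },
    stop(sprintf("unknown kind '%s'", obj$kind)))
}

encode_value <- function(v) {
  if (is.data.frame(v)) {
    list(kind = "table", columns = I(names(v)), data = lapply(v, I))
  } else if (is.matrix(v)) {
    d <- as.data.frame(v, stringsAsFactors = FALSE)
    list(kind = "table", columns = I(names(d)), data = lapply(d, I))
  } else if (is.integer(v)) {
    list(kind = "integer", value = I(v))
  } else if (is.numeric(v)) {
    list(kind = "numeric", value = I(v))
  } else if (is.logical(v)) {
    list(kind = "logical", value = I(v))
  } else if (is.character(v) || is.factor(v)) {
    list(kind = "character", value = I(as.character(v)))
  } else {
    stop("unsupported value type")
  }
}

repeat {
  body <- read_frame()
  if (is.null(body)) break
  nl <- regexpr("\n", body, fixed = TRUE)
  if (nl > 0) {
    head <- substr(body, 1, nl - 1)
    payload <- substr(body, nl + 1, nchar(body))
  } else {
    head <- body
    payload <- ""
  }
  parts <- strsplit(head, " ", fixed = TRUE)[[1]]
  cmd <- parts[1]
  res <- tryCatch({
    if (cmd == "SET") {
      obj <- fromJSON(payload, simplifyVector = TRUE)
      assign(parts[2], decode_value(obj), envir = globalenv())
      list(ok = TRUE, text = "")
    } else if (cmd == "EVAL") {
      txt <- paste(capture.output(
        source(textConnection(payload), local = globalenv(),
               echo = FALSE, print.eval = TRUE)
      ), collapse = "\n")
      list(ok = TRUE, text = txt)
    } else if (cmd == "GET") {
      if (!exists(parts[2], envir = globalenv()))
        stop(sprintf("no session variable named '%s'", parts[2]))
      v <- get(parts[2], envir = globalenv())
      list(ok = TRUE,
           text = as.character(toJSON(encode_value(v), na = "null",
                                      auto_unbox = FALSE, digits = NA)))
    } else if (cmd == "CLOSE") {
      quit(save = "no", status = 0)
    } else {
      stop(sprintf("unknown command '%s'", cmd))
    }
  }, error = function(e) list(ok = FALSE, text = conditionMessage(e)))
  send(if (res$ok) "OK" else "ERR", res$text)
}
"""


def _json_safe(obj):
    """Recursively replace NaN/numpy scalars so json + jsonlite interoperate."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _encode_json(value: BackendValue) -> str:
    if value.kind == "table":
        df = value.value
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        doc = {
            "kind": "table",
            "columns": [str(c) for c in df.columns],
            "data": {str(c): df[c].tolist() for c in df.columns},
        }
    elif value.kind == "vector":
        doc = {"kind": "vector", "value": list(np.asarray(value.value, dtype=float))}
    else:
        doc = {"kind": value.kind, "value": [value.value]}
    return json.dumps(_json_safe(doc))


def _decode_json(text: str):
    doc = json.loads(text)
    kind = doc["kind"]
    if isinstance(kind, list):  # jsonlite encodes scalars as length-1 arrays
        kind = kind[0]
    if kind == "table":
        columns = doc["columns"]
        data = {c: doc["data"][c] for c in columns}
        df = pd.DataFrame(data)
        return df
    vals = doc["value"]
    vals = [np.nan if v is None else v for v in vals]
    if kind in ("integer", "numeric", "logical", "character") and len(vals) == 1:
        return vals[0]
    if kind in ("integer", "numeric", "vector"):
        return list(np.asarray(vals, dtype=float))
    return vals


def r_available() -> bool:
    return shutil.which("Rscript") is not None


class RBackend(Backend):
    """An R session as an ``Rscript`` subprocess.

    Frames are ``<byte-count>\\n<body>``; the body's first line is the
    command (``SET name`` / ``EVAL`` / ``GET name`` / ``CLOSE``) and the rest
    is the payload (JSON for values, source text for EVAL). Responses are
    ``OK <n>`` or ``ERR <n>`` followed by ``n`` bytes. Cancellation
    terminates the subprocess (the engine only cancels at unit boundaries).
    """

    def __init__(self, rscript: str = "Rscript", timeout: float = 120.0):
        self.rscript = rscript
        self.timeout = timeout
        self.proc: subprocess.Popen | None = None
        self._driver_path: Path | None = None
        self._cancelled = False

    def open(self) -> None:
        if self.proc is not None:
            return
        if not shutil.which(self.rscript):
            raise BackendError(f"R runtime not found: {self.rscript!r}")
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".R", prefix="tabbench_driver_", delete=False
        )
        tmp.write(_R_DRIVER)
        tmp.close()
        self._driver_path = Path(tmp.name)
        self.proc = subprocess.Popen(
            [self.rscript, "--vanilla", str(self._driver_path)],
            stdin=subprocess.PIPE,
            stdout=subprocess.PIPE,
            stderr=subprocess.DEVNULL,
        )

    def close(self) -> None:
        if self.proc is not None:
            try:
                self._send("CLOSE")
            except Exception:
                pass
            try:
                self.proc.terminate()
                self.proc.wait(timeout=5)
            except Exception:
                self.proc.kill()
            self.proc = None
        if self._driver_path is not None:
            self._driver_path.unlink(missing_ok=True)
            self._driver_path = None

    def cancel(self) -> None:
        self._cancelled = True
        if self.proc is not None:
            self.proc.kill()
            self.proc = None

    # -- wire protocol -----------------------------------------------------

    def _send(self, head: str, payload: str = "") -> None:
        assert self.proc is not None and self.proc.stdin is not None
        body = (head + "\n" + payload).encode("utf-8")
        self.proc.stdin.write(f"{len(body)}\n".encode("ascii"))
        self.proc.stdin.write(body)
        self.proc.stdin.flush()

    def _recv(self) -> tuple[str, str]:
        assert self.proc is not None and self.proc.stdout is not None
        header = self.proc.stdout.readline().decode("utf-8").strip()
        if not header:
            raise BackendError("R session closed unexpectedly")
        status, nbytes = header.split(" ", 1)
        body = self.proc.stdout.read(int(nbytes)).decode("utf-8")
        self.proc.stdout.read(1)  # trailing newline
        return status, body

    def _roundtrip(self, head: str, payload: str = "") -> str:
        if self.proc is None:
            raise BackendError("session is not open")
        self._send(head, payload)
        status, body = self._recv()
        if status != "OK":
            raise BackendError(body, output=body)
        return body

    # -- contract ----------------------------------------------------------

    def set_value(self, name: str, value: BackendValue) -> None:
        self._roundtrip(f"SET {name}", _encode_json(value))

    def evaluate(self, code: str) -> str:
        return self._roundtrip("EVAL", code)

    def fetch(self, name: str):
        return _decode_json(self._roundtrip(f"GET {name}"))
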