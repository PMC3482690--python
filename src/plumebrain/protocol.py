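"""ASCII line protocol between the virtual world and the neural simulation.

Per timestep only tens of bytes cross the link: the world sends one
``SENSE c1 c2 c3\\n`` line (fixed 6-decimal floats, one value per odorant
channel) and the brain answers ``MOTOR l r\\n`` with the signed 8-bit net
tread currents.  The protocol is ASCII over TCP so either side can be
reimplemented in any language; an in-process coupling with identical
semantics is provided by passing any controller object directly to
``run_trial``.
"""

from __future__ import annotations

import socket
import socketserver
import threading
import warnings

import numpy as np

__all__ = [
    "ProtocolError",
    "encode_sense_message",
    "decode_sense_message",
    "encode_motor_message",
    "decode_motor_message",
    "BrainServer",
    "SocketController",
]


class ProtocolError(ValueError):
    """Malformed SENSE/MOTOR line."""


def encode_sense_message(concentrations) -> bytes:
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1 or not np.all(np.isfinite(c)):
        raise ProtocolError("concentrations must be a finite 1-D vector")
    body = " ".join(f"{x:.6f}" for x in c)
    return f"SENSE {body}\n".encode("ascii")


def decode_sense_message(data: bytes) -> np.ndarray:
    parts = data.decode("ascii", errors="replace").strip().split()
    if len(parts) < 2 or parts[0] != "SENSE":
        raise ProtocolError(f"malformed SENSE line: {data!r}")
    try:
        return np.array([float(p) for p in parts[1:]], dtype=float)
    except ValueError as exc:
        raise ProtocolError(f"malformed SENSE line: {data!r}") from exc


def encode_motor_message(current_left: int, current_right: int) -> bytes:
    i_l, i_r = int(current_left), int(current_right)
    if abs(i_l) > 127 or abs(i_r) > 127:
        warnings.warn("motor current outside signed 8-bit range; clamping", RuntimeWarning, stacklevel=2)
        i_l = int(np.clip(i_l, -127, 127))
        i_r = int(np.clip(i_r, -127, 127))
    return f"MOTOR {i_l} {i_r}\n".encode("ascii")


def decode_motor_message(data: bytes) -> tuple[int, int]:
    parts = data.decode("ascii", errors="replace").strip().split()
    if len(parts) != 3 or parts[0] != "MOTOR":
        raise ProtocolError(f"malformed MOTOR line: {data!r}")
    try:
        i_l, i_r = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ProtocolError(f"malformed MOTOR line: {data!r}") from exc
    if abs(i_l) > 127 or abs(i_r) > 127:
        warnings.warn("motor current outside signed 8-bit range; clamping", RuntimeWarning, stacklevel=2)
        i_l = int(np.clip(i_l, -127, 127))
        i_r = int(np.clip(i_r, -127, 127))
    return i_l, i_r


class BrainServer:
    """Serves a controller over TCP: reads SENSE lines, answers MOTOR lines.

    The wrapped controller sees the same ``command`` interface as the
    in-process coupling (proximity is not part of the wire protocol and is
    reported as +inf).  A ``SEED n`` line resets the controller; the
    connection closes on EOF or a ``BYE`` line.
    """

    def __init__(self, controller, dt: float = 0.030, host: str = "127.0.0.1", port: int = 0):
        self.controller = controller
        self.dt = dt
        outer = self

        class _Handler(socketserver.StreamRequestHandler):
            def handle(self) -> None:
                while True:
                    line = self.rfile.readline()
                    if not line:
                        return
                    text = line.decode("ascii", errors="replace").strip()
                    if text == "BYE":
                        return
                    if text.startswith("SEED"):
                        parts = text.split()
                        outer.controller.reset(int(parts[1]) if len(parts) > 1 else None)
                        self.wfile.write(b"OK\n")
                        continue
                    conc = decode_sense_message(line)
                    i_l, i_r = outer.controller.command(conc, float("inf"), outer.dt)
                    self.wfile.write(encode_motor_message(i_l, i_r))

        self._server = socketserver.TCPServer((host, port), _Handler)
        self._server.daemon_threads = True
        self._thread: threading.Thread | None = None

    @property
    def address(self) -> tuple[str, int]:
        return self._server.server_address

    def start(self) -> "BrainServer":
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5.0)

    def __enter__(self) -> "BrainServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


class SocketController:
    """World-side controller proxy: forwards SENSE over TCP, reads MOTOR.

    Drop-in for ``run_trial``; with the same remote controller and seed it
    produces the same trial as the in-process coupling.
    """

    def __init__(self, host: str, port: int, timeout: float = 10.0):
        self._addr = (host, port)
        self._timeout = timeout
        self._sock: socket.socket | None = None
        self._file = None

    def _connect(self) -> None:
        self.close()
        self._sock = socket.create_connection(self._addr, timeout=self._timeout)
        self._file = self._sock.makefile("rb")

    def reset(self, seed: int | None) -> None:
        self._connect()
        self._sock.sendall(f"SEED {seed if seed is not None else ''}\n".strip().encode() + b"\n")
        ack = self._file.readline()
        if ack.strip() != b"OK":
            raise ProtocolError(f"expected OK after SEED, got {ack!r}")

    def command(self, concentrations, proximity, dt) -> tuple[int, int]:  # noqa: ARG002
        if self._sock is None:
            raise ProtocolError("SocketController used before reset()")
        self._sock.sendall(encode_sense_message(concentrations))
        line = self._file.readline()
        if not line:
            raise ProtocolError("connection closed by brain server")
        return decode_motor_message(line)

    def close(self) -> None:
        if self._file is not None:
            self._file.close()
            self._file = None
        if self._sock is not None:
            self._sock.close()
            self._sock = None

    def __enter__(self) -> "SocketController":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
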